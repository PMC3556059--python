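"""General data-processing operations on feature tracks.

These are the workhorse transforms a regulatory-sequence workflow
composes: masking DNA, filtering and reshaping region tracks, numeric
track arithmetic and smoothing, conversions between track kinds, and
per-sequence summary statistics.  All operations are pure: inputs are
never mutated, and identical arguments give identical results (masking
with a background fill requires an explicit seed for that reason).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .conditions import Condition, TrueCondition, eval_condition
from .core import (CiskitError, Collection, DNATrack, NumericMap, NumericTrack,
                   Region, RegionTrack)

_WINDOW_STATS = {
    "mean": np.mean, "median": np.median, "min": np.min, "max": np.max, "sum": np.sum,
}


def _positions_where(cond, env, seq_name: str, length: int) -> np.ndarray:
    return np.fromiter(
        (eval_condition(cond, env, seq_name, i) for i in range(length)),
        dtype=bool, count=length)


def mask(dna: DNATrack, fill, where, seed: Optional[int] = None, env=None) -> DNATrack:
    """Replace selected bases with a letter (e.g. 'N' or 'X') or with
    random bases sampled from a Markov background model.

    ``where`` is a position condition or a RegionTrack (mask everything
    covered by its regions — the classic repeat-masking use).  Background
    fill samples each masked position left to right, conditioning on the
    (possibly already masked) preceding context, and requires ``seed``.
    """
    from .motifs import BackgroundModel  # local import avoids cycle

    use_background = isinstance(fill, BackgroundModel)
    if use_background and seed is None:
        raise CiskitError("background fill requires an explicit seed")
    if not use_background:
        if not isinstance(fill, str) or len(fill) != 1 or fill.upper() not in "ACGTNX":
            raise CiskitError(f"fill must be a single DNA letter or a background model")
    rng = np.random.default_rng(seed) if use_background else None

    out: Dict[str, str] = {}
    for seq in dna.sequences:
        s = dna[seq.name]
        if isinstance(where, RegionTrack):
            flags = np.zeros(len(s), dtype=bool)
            for r in where[seq.name]:
                flags[r.start:r.end] = True
        else:
            flags = _positions_where(where, env or {}, seq.name, len(s))
        chars = list(s)
        k = fill.order if use_background else 0
        for i in np.flatnonzero(flags):
            if use_background:
                context = "".join(chars[max(0, i - k):i])
                chars[i] = fill.sample_base(context, rng)
            else:
                chars[i] = fill
        out[seq.name] = "".join(chars)
    return DNATrack(dna.sequences, out)


def filter_regions(track: RegionTrack, where: Condition, env=None) -> RegionTrack:
    """Keep only the regions satisfying a region-context condition."""
    out = {}
    for name in track.names:
        out[name] = [r.copy() for r in track[name]
                     if eval_condition(where, env or {}, name, r)]
    return RegionTrack(track.sequences, out)


def extend_regions(track: RegionTrack, up: int = 0, down: int = 0,
                   strand_aware: bool = False) -> RegionTrack:
    """Extend every region by ``up`` bp before its start and ``down`` bp
    after its end (swapped for minus-strand regions when strand_aware),
    clipping at sequence bounds."""
    if up < 0 or down < 0:
        raise CiskitError("extension amounts must be >= 0")
    out = {}
    for seq in track.sequences:
        regions = []
        for r in track[seq.name]:
            u, d = (down, up) if (strand_aware and r.strand == "-") else (up, down)
            r2 = r.copy()
            r2.start = max(0, r.start - u)
            r2.end = min(seq.length, r.end + d)
            regions.append(r2)
        out[seq.name] = regions
    return RegionTrack(track.sequences, out)


def merge_regions(track: RegionTrack, max_gap: int = 0) -> RegionTrack:
    """Union regions whose nearest-edge gap is <= max_gap.

    The merged region keeps the max member score; the type is kept only
    when unanimous (else "merged"), likewise strand (else '.').
    """
    if max_gap < 0:
        raise CiskitError("max_gap must be >= 0")
    out = {}
    for name in track.names:
        merged: List[Region] = []
        for r in sorted(track[name], key=Region.sort_key):
            if merged and r.start - merged[-1].end <= max_gap:
                m = merged[-1]
                m.end = max(m.end, r.end)
                m.score = max(m.score, r.score)
                if m.type != r.type:
                    m.type = "merged"
                if m.strand != r.strand:
                    m.strand = "."
            else:
                merged.append(Region(r.start, r.end, r.type, r.score, r.strand))
        out[name] = merged
    return RegionTrack(track.sequences, out)


def transform_regions(track: RegionTrack, op: str, **kwargs) -> RegionTrack:
    if op == "extend":
        return extend_regions(track, **kwargs)
    if op == "merge":
        return merge_regions(track, **kwargs)
    raise CiskitError(f"unknown region transform {op!r}")


def arithmetic(track: NumericTrack, op: str, operand=None, where=None, env=None,
               target: Optional[tuple] = None) -> NumericTrack:
    """Apply an arithmetic transform per position.

    ``operand`` may be a scalar, another NumericTrack (positionwise) or a
    NumericMap (per-sequence scalar).  ``where`` restricts the affected
    positions.  ``range_normalize`` maps the observed [min, max] over all
    sequences jointly onto the ``target`` interval.
    """
    out = {}
    if op == "range_normalize":
        lo, hi = target if target is not None else (0.0, 1.0)
        allv = np.concatenate([track[n] for n in track.names])
        mn, mx = float(allv.min()), float(allv.max())
        span = mx - mn
        for name in track.names:
            v = track[name].copy()
            if span == 0:
                newv = np.full_like(v, (lo + hi) / 2.0)
            else:
                newv = lo + (v - mn) * (hi - lo) / span
            out[name] = _apply_where(v, newv, where, env, name)
        return NumericTrack(track.sequences, out)

    for name in track.names:
        v = track[name]
        o = operand
        if isinstance(o, NumericTrack):
            o = o[name]
        elif isinstance(o, NumericMap):
            o = o[name]
        if op == "add":
            newv = v + o
        elif op == "sub":
            newv = v - o
        elif op == "mul":
            newv = v * o
        elif op == "div":
            flags = _where_flags(where, env, name, len(v))
            if np.any(np.asarray(o == 0) & flags) if np.ndim(o) else (o == 0 and flags.any()):
                bad = int(np.flatnonzero(np.asarray(o == 0) & flags)[0]) if np.ndim(o) else int(np.flatnonzero(flags)[0])
                raise CiskitError(f"division by zero in sequence {name!r} at position {bad}")
            with np.errstate(divide="ignore", invalid="ignore"):
                newv = np.where(flags, v / np.where(np.asarray(o) == 0, 1, o) if np.ndim(o) else v / o, v)
            out[name] = newv
            continue
        elif op == "min":
            newv = np.minimum(v, o)
        elif op == "max":
            newv = np.maximum(v, o)
        elif op == "log":
            flags = _where_flags(where, env, name, len(v))
            if np.any((v <= 0) & flags):
                bad = int(np.flatnonzero((v <= 0) & flags)[0])
                raise CiskitError(f"log of non-positive value in sequence {name!r} at position {bad}")
            newv = np.where(flags, np.log(np.where(v <= 0, 1, v)), v)
            out[name] = newv
            continue
        else:
            raise CiskitError(f"unknown arithmetic op {op!r}")
        out[name] = _apply_where(v, newv, where, env, name)
    return NumericTrack(track.sequences, out)


def _where_flags(where, env, name, length) -> np.ndarray:
    if where is None:
        return np.ones(length, dtype=bool)
    return _positions_where(where, env or {}, name, length)


def _apply_where(old: np.ndarray, new: np.ndarray, where, env, name) -> np.ndarray:
    if where is None:
        return new
    flags = _positions_where(where, env or {}, name, len(old))
    return np.where(flags, new, old)


def sliding_window(track: NumericTrack, stat: str = "mean", size: int = 3) -> NumericTrack:
    """Centered sliding-window smoothing; the window shrinks (is clipped)
    at sequence edges so the output has the same length as the input."""
    if size < 1 or size % 2 == 0:
        raise CiskitError("window size must be odd and >= 1")
    if stat not in _WINDOW_STATS:
        raise CiskitError(f"unknown window statistic {stat!r}")
    half = size // 2
    fn = _WINDOW_STATS[stat]
    out = {}
    for name in track.names:
        v = track[name]
        n = len(v)
        if stat in ("mean", "sum"):
            csum = np.concatenate(([0.0], np.cumsum(v)))
            lo = np.maximum(0, np.arange(n) - half)
            hi = np.minimum(n, np.arange(n) + half + 1)
            sums = csum[hi] - csum[lo]
            out[name] = sums / (hi - lo) if stat == "mean" else sums
        else:
            out[name] = np.array([fn(v[max(0, i - half):min(n, i + half + 1)])
                                  for i in range(n)])
    return NumericTrack(track.sequences, out)


def combine_tracks(tracks: Sequence[NumericTrack], weights: Sequence[float]) -> NumericTrack:
    """Per-position weighted sum of several numeric tracks."""
    if len(tracks) != len(weights):
        raise CiskitError("need exactly one weight per track")
    if not tracks:
        raise CiskitError("need at least one track")
    base = tracks[0]
    out = {}
    for name in base.names:
        acc = np.zeros(len(base[name]))
        for t, w in zip(tracks, weights):
            if len(t[name]) != len(acc):
                raise CiskitError(f"track length mismatch on sequence {name!r}")
            acc += w * t[name]
        out[name] = acc
    return NumericTrack(base.sequences, out)


def numeric_to_regions(track: NumericTrack, threshold: float,
                       min_length: int = 1, type: str = "run") -> RegionTrack:
    """Turn maximal runs of positions with value >= threshold (and run
    length >= min_length) into regions scored by the run mean."""
    if min_length < 1:
        raise CiskitError("min_length must be >= 1")
    out = {}
    for name in track.names:
        v = track[name]
        above = v >= threshold
        regions = []
        i = 0
        n = len(v)
        while i < n:
            if above[i]:
                j = i
                while j < n and above[j]:
                    j += 1
                if j - i >= min_length:
                    regions.append(Region(i, j, type, float(np.mean(v[i:j]))))
                i = j
            else:
                i += 1
        out[name] = regions
    return RegionTrack(track.sequences, out)


def regions_to_numeric(track: RegionTrack, mode: str = "coverage") -> NumericTrack:
    """Project region evidence to a per-position signal: ``coverage`` =
    number of covering regions, ``max_score`` = best covering score."""
    out = {}
    for seq in track.sequences:
        v = np.zeros(seq.length)
        for r in track[seq.name]:
            if mode == "coverage":
                v[r.start:r.end] += 1
            elif mode == "max_score":
                v[r.start:r.end] = np.maximum(v[r.start:r.end], r.score)
            else:
                raise CiskitError(f"unknown mode {mode!r}")
        out[seq.name] = v
    return NumericTrack(track.sequences, out)


def sequence_statistic(dna: DNATrack, stat: str = "gc_content",
                       base: Optional[str] = None) -> NumericMap:
    """Per-sequence summary: GC fraction (N/X excluded from both
    numerator and denominator), length, or a single-base count."""
    values = {}
    for name in dna.names:
        s = dna[name].upper()
        if stat == "gc_content":
            acgt = sum(s.count(b) for b in "ACGT")
            values[name] = (s.count("G") + s.count("C")) / acgt if acgt else 0.0
        elif stat == "length":
            values[name] = float(len(s))
        elif stat == "count_base":
            if base is None:
                raise CiskitError("count_base requires a base")
            values[name] = float(s.count(base.upper()))
        else:
            raise CiskitError(f"unknown sequence statistic {stat!r}")
    return NumericMap("sequence", values)


def collection_from_map(nmap: NumericMap, op: str, value: float,
                        member_type: Optional[str] = None) -> Collection:
    """Members of a numeric map whose value satisfies a comparison, as a
    collection (e.g. sequences with GC-content < 0.40)."""
    import operator
    ops = {"<": operator.lt, "<=": operator.le, ">": operator.gt,
           ">=": operator.ge, "=": operator.eq, "==": operator.eq, "!=": operator.ne}
    if op not in ops:
        raise CiskitError(f"unknown comparison {op!r}")
    members = {m for m, v in nmap.items() if ops[op](v, value)}
    return Collection(member_type or nmap.member_type, members)
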