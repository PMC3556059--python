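"""Motif scanning and Markov background models.

Scoring convention
------------------
A window ``b_1..b_w`` is scored against a motif ``M`` with the log-odds
sum ``S = sum_i log(M[b_i, i] / Q(b_i))`` where ``Q`` is the order-0 view
of the background model (uniform if none is given).  The *relative*
score ``r = (S - S_min) / (S_max - S_min)`` rescales S between the worst
and best achievable window scores of that motif, so ``r`` is in [0, 1],
the consensus-best window scores exactly 1, and a "80% match" threshold
means ``r >= 0.8``.  Unknown bases (N/X) contribute 0 to S, i.e. they
score as the background expectation.

Whether relative scores are normalized on the log-odds scale (default)
or on the raw window-probability scale is configurable via the
``scale`` argument of :func:`scan_motifs` / :func:`pwm_score_profile`.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (BASE_INDEX, BASES, CiskitError, DNATrack, IUPAC_CODES, Motif,
                   MotifCollectionObj, Region, RegionTrack, reverse_complement)

logger = logging.getLogger("ciskit")

COUNT_PSEUDOCOUNT = 0.25   # added per cell to raw count matrices
PROB_PSEUDOCOUNT = 0.01    # added per cell to probability matrices


def normalize_matrix(matrix: np.ndarray, kind: str = "counts") -> np.ndarray:
    """Column-normalize a 4 x w matrix with the documented pseudocounts.

    ``kind='counts'`` adds 0.25 per cell (raw count matrices from JASPAR
    or aligned sites); ``kind='probabilities'`` adds 0.01 per cell and
    renormalizes (matrices that already sum to ~1 per column).
    """
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise CiskitError("matrix entries must be non-negative")
    if np.any(m.sum(axis=0) == 0):
        raise CiskitError("matrix column sums to 0")
    pc = COUNT_PSEUDOCOUNT if kind == "counts" else PROB_PSEUDOCOUNT
    m = m + pc
    return m / m.sum(axis=0, keepdims=True)


class BackgroundModel:
    """Order-k Markov chain over A,C,G,T with complete conditional
    tables and lower-order fallbacks for sequence starts.

    ``tables[j]`` maps every length-j ACGT context to a probability
    vector over the next base; all cells are pseudocount-smoothed so no
    probability is ever zero.
    """

    def __init__(self, order: int, tables: List[Dict[str, np.ndarray]],
                 trained_on: str = ""):
        if order < 0 or order > 5:
            raise CiskitError("background order must be in [0, 5]")
        self.order = order
        self.tables = tables
        self.trained_on = trained_on
        for j, table in enumerate(tables):
            for ctx, p in table.items():
                if len(ctx) != j or abs(p.sum() - 1.0) > 1e-9 or np.any(p <= 0):
                    raise CiskitError(f"bad conditional distribution for context {ctx!r}")

    @property
    def order0(self) -> np.ndarray:
        """Stationary order-0 base distribution (the fallback table)."""
        return self.tables[0][""]

    def conditional(self, context: str) -> np.ndarray:
        """P(next base | context), falling back to lower orders when the
        usable clean context is shorter than the model order."""
        context = context.upper()
        for j in range(min(self.order, len(context)), -1, -1):
            ctx = context[len(context) - j:]
            if all(c in BASE_INDEX for c in ctx):
                return self.tables[j][ctx]
        return self.tables[0][""]

    def sample_base(self, prefix: str, rng: np.random.Generator) -> str:
        return BASES[rng.choice(4, p=self.conditional(prefix))]

    def log_likelihood(self, s: str) -> float:
        s = s.upper()
        total = 0.0
        for i, c in enumerate(s):
            if c not in BASE_INDEX:
                continue
            total += float(np.log(self.conditional(s[:i])[BASE_INDEX[c]]))
        return total


def train_background(dna: DNATrack, order: int) -> BackgroundModel:
    """Train an order-k background model on the forward strands of a DNA
    track, with +1 pseudocount per context cell and complete lower-order
    fallback tables for scoring/sampling sequence starts."""
    if order < 0 or order > 5:
        raise CiskitError("background order must be in [0, 5]")
    seqs = [dna[name].upper() for name in dna.names]
    total_len = sum(len(s) for s in seqs)
    if total_len == 0:
        raise CiskitError("cannot train a background model on empty input")
    if total_len <= 4 ** (order + 1):
        logger.warning("background training data (%d bp) is small for order %d",
                       total_len, order)
    tables: List[Dict[str, np.ndarray]] = []
    for j in range(order + 1):
        counts = {"".join(ctx): np.ones(4)  # +1 pseudocount per cell
                  for ctx in itertools.product(BASES, repeat=j)}
        for s in seqs:
            for i in range(j, len(s)):
                ctx, b = s[i - j:i], s[i]
                if b in BASE_INDEX and ctx in counts:
                    counts[ctx][BASE_INDEX[b]] += 1
        tables.append({ctx: c / c.sum() for ctx, c in counts.items()})
    return BackgroundModel(order, tables, trained_on=f"{len(seqs)} sequences, {total_len} bp")


def sample_background(model: BackgroundModel, length: int, seed: int) -> str:
    """Sample a DNA string from the background model; deterministic for
    a fixed seed, using the fallback tables for the first k bases."""
    if length < 1:
        raise CiskitError("length must be >= 1")
    if seed is None:
        raise CiskitError("sampling requires a seed")
    rng = np.random.default_rng(seed)
    cumtables = [{ctx: np.cumsum(p) for ctx, p in table.items()}
                 for table in model.tables]
    out: List[str] = []
    k = model.order
    for i in range(length):
        j = min(k, i)
        ctx = "".join(out[i - j:i])
        cum = cumtables[j][ctx]
        out.append(BASES[int(np.searchsorted(cum, rng.random()))])
    return "".join(out)


# ------------------------------------------------------------------ scoring

def _encode(s: str) -> np.ndarray:
    """Map a DNA string to indices 0..3; unknown letters become -1."""
    arr = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        codes[arr == ord(b)] = i
    return codes


_PROB_FLOOR = 1e-9  # keeps hard-zero matrix cells finite in log space


def _odds_matrix(motif: Motif, q: np.ndarray, scale: str) -> np.ndarray:
    m = np.maximum(motif.matrix, _PROB_FLOOR)
    if scale == "logodds":
        return np.log(m / q[:, None])
    if scale == "probability":
        return m / q[:, None]
    raise CiskitError(f"unknown score scale {scale!r}")


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Sum log-odds over all windows; unknown bases contribute 0."""
    w = lo.shape[1]
    n = codes.size - w + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    for j in range(w):
        c = codes[j:j + n]
        scores += np.where(c >= 0, lo[np.clip(c, 0, 3), j], 0.0)
    return scores


def _score_bounds(lo: np.ndarray) -> Tuple[float, float]:
    return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())


def relative_score_params(motif: Motif, background: Optional[BackgroundModel] = None,
                          scale: str = "logodds"):
    """Log-odds matrix and (S_min, S_max) bounds for min-max rescaling."""
    q = background.order0 if background is not None else np.full(4, 0.25)
    lo = _odds_matrix(motif, q, scale)
    smin, smax = _score_bounds(lo)
    return lo, smin, smax


def scan_motifs(dna: DNATrack, motifs: Iterable[Motif], threshold: float,
                background: Optional[BackgroundModel] = None,
                strands: str = "both", scale: str = "logodds") -> RegionTrack:
    """Scan sequences with a motif library; every window whose relative
    score reaches the threshold becomes a region typed by motif id.

    Reverse-strand windows are scored on the reverse complement but
    reported in forward coordinates with strand '-'.  Overlapping and
    double-strand hits are all kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise CiskitError("threshold must be in [0, 1]")
    if strands not in ("both", "forward"):
        raise CiskitError("strands must be 'both' or 'forward'")
    out: Dict[str, List[Region]] = {name: [] for name in dna.names}
    for motif in motifs:
        lo, smin, smax = relative_score_params(motif, background, scale)
        if smax - smin <= 0:
            logger.warning("motif %s is uninformative (S_max == S_min); skipped", motif.id)
            continue
        w = motif.width
        lo_rc = lo[::-1, ::-1]  # score of revcomp window on the forward strand
        for name in dna.names:
            codes = _encode(dna[name])
            fwd = (_window_scores(codes, lo) - smin) / (smax - smin)
            for i in np.flatnonzero(fwd >= threshold):
                out[name].append(Region(int(i), int(i) + w, motif.id,
                                        float(fwd[i]), "+"))
            if strands == "both":
                rev = (_window_scores(codes, lo_rc) - smin) / (smax - smin)
                for i in np.flatnonzero(rev >= threshold):
                    out[name].append(Region(int(i), int(i) + w, motif.id,
                                            float(rev[i]), "-"))
    return RegionTrack(dna.sequences, out)


def match_consensus(dna: DNATrack, pattern: str, strands: str = "both") -> RegionTrack:
    """Exact IUPAC matching of a consensus pattern (N matches anything).

    With ``strands='both'`` the reverse orientation is found by matching
    the reverse-complemented pattern on the forward strand; palindromic
    patterns yield a single '+' hit per window.
    """
    pattern = pattern.upper()
    for c in pattern:
        if c not in IUPAC_CODES:
            raise CiskitError(f"invalid IUPAC character {c!r}")
    pat_rc = reverse_complement(pattern)
    out: Dict[str, List[Region]] = {}
    for name in dna.names:
        s = dna[name].upper()
        hits = []
        for i in range(len(s) - len(pattern) + 1):
            window = s[i:i + len(pattern)]
            if _iupac_match(window, pattern):
                hits.append(Region(i, i + len(pattern), pattern, 1.0, "+"))
            if strands == "both" and pat_rc != pattern and _iupac_match(window, pat_rc):
                hits.append(Region(i, i + len(pattern), pattern, 1.0, "-"))
        out[name] = hits
    return RegionTrack(dna.sequences, out)


def _iupac_match(window: str, pattern: str) -> bool:
    return all(w in IUPAC_CODES[p] for w, p in zip(window, pattern))


def motif_from_sites(aligned: Sequence[str], id: str) -> Motif:
    """Build a motif from equal-length aligned binding sequences, with
    0.25 pseudocount per matrix cell."""
    if not aligned:
        raise CiskitError("need at least one site")
    w = len(aligned[0])
    if any(len(s) != w for s in aligned):
        raise CiskitError("aligned sites must have equal lengths")
    counts = np.zeros((4, w))
    for s in aligned:
        s = s.upper()
        for j, c in enumerate(s):
            if c not in BASE_INDEX:
                raise CiskitError(f"site {s!r}: only A,C,G,T allowed")
            counts[BASE_INDEX[c], j] += 1
    return Motif(id, normalize_matrix(counts, "counts"))


def pwm_score_profile(dna: DNATrack, motif: Motif,
                      background: Optional[BackgroundModel] = None,
                      scale: str = "logodds"):
    """Per-position best-strand relative score of the window starting at
    each position (the trailing w-1 positions hold 0); feeds conditions
    and priors construction."""
    from .core import NumericTrack

    lo, smin, smax = relative_score_params(motif, background, scale)
    out = {}
    if smax - smin <= 0:
        logger.warning("motif %s is uninformative; profile is all zero", motif.id)
        for name in dna.names:
            out[name] = np.zeros(len(dna[name]))
        return NumericTrack(dna.sequences, out)
    lo_rc = lo[::-1, ::-1]
    for name in dna.names:
        codes = _encode(dna[name])
        v = np.zeros(codes.size)
        fwd = (_window_scores(codes, lo) - smin) / (smax - smin)
        rev = (_window_scores(codes, lo_rc) - smin) / (smax - smin)
        if fwd.size:
            v[:fwd.size] = np.maximum(fwd, rev)
        out[name] = v
    return NumericTrack(dna.sequences, out)
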