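"""Cis-regulatory module models, constraint scanning, and
interaction-partner filtering.

A cis-regulatory module (CRM) is a group of binding sites for
co-operating transcription factors occurring in close proximity.  A
:class:`ModuleModel` declares the module's composition as ordered
*slots*, each filled by any of a set of alternative motifs, together
with constraints on the overall span, the order of the sites along the
sequence, per-slot strand orientations, and nearest-edge gaps between
adjacent sites.  Scanning takes an existing motif track (binding-site
predictions) and emits every combination of candidate sites that
satisfies the model.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .conditions import nearest_edge_gap
from .core import CiskitError, Region, RegionTrack

_INF = 10 ** 9


@dataclass
class ModuleModel:
    """Declarative model of a cis-regulatory module.

    ``slots`` lists the alternative motif ids allowed at each position
    of the module; ``gaps[i]`` bounds the nearest-edge distance between
    the genomically adjacent pair (i, i+1) of member sites (for ordered
    models that pair is slot i and slot i+1); ``orientations[i]`` pins
    the strand of slot i's site ('+', '-', or 'any').
    """

    id: str
    slots: List[Set[str]]
    max_span: int = _INF
    ordered: bool = True
    orientations: Optional[List[str]] = None
    gaps: Optional[List[Tuple[int, int]]] = None

    def __post_init__(self):
        if len(self.slots) < 2:
            raise CiskitError("a module needs at least 2 slots")
        self.slots = [set(s) for s in self.slots]
        if self.orientations is None:
            self.orientations = ["any"] * len(self.slots)
        if len(self.orientations) != len(self.slots):
            raise CiskitError("need one orientation per slot")
        for o in self.orientations:
            if o not in ("+", "-", "any"):
                raise CiskitError(f"bad orientation {o!r}")
        if self.gaps is None:
            self.gaps = [(0, _INF)] * (len(self.slots) - 1)
        if len(self.gaps) != len(self.slots) - 1:
            raise CiskitError("need one gap constraint per adjacent slot pair")
        for lo, hi in self.gaps:
            if lo < 0 or hi < lo:
                raise CiskitError(f"bad gap constraint ({lo}, {hi})")
        if self.max_span < 0:
            raise CiskitError("max_span must be >= 0")

    def motif_ids(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.slots:
            out |= s
        return out


def scan_modules(motif_track: RegionTrack, model: ModuleModel,
                 known_motifs: Optional[Sequence[str]] = None,
                 score_mode: str = "sum") -> RegionTrack:
    """Find all module occurrences among predicted binding sites.

    Every selection of one distinct site per slot that satisfies the
    span / order / orientation / gap constraints becomes a module region
    spanning its member sites, carrying them as children.  Two
    occurrences with the same member-site set are emitted once; sharing
    only some sites keeps both.  Module score is the sum (or mean/min,
    per ``score_mode``) of member scores.
    """
    if known_motifs is not None:
        missing = model.motif_ids() - set(known_motifs)
        if missing:
            raise CiskitError(f"module references unknown motifs: {sorted(missing)}")
    if score_mode not in ("sum", "mean", "min"):
        raise CiskitError(f"unknown score mode {score_mode!r}")

    out: Dict[str, List[Region]] = {}
    for name in motif_track.names:
        sites = motif_track[name]
        candidates = [[r for r in sites
                       if r.type in slot and _orientation_ok(r, orient)]
                      for slot, orient in zip(model.slots, model.orientations)]
        seen: Set[tuple] = set()
        occurrences = []
        for combo in itertools.product(*candidates):
            if len({id(r) for r in combo}) != len(combo):
                continue  # one physical site cannot fill two slots
            if not _satisfies(combo, model):
                continue
            key = tuple(sorted((r.start, r.end, r.type, r.strand) for r in combo))
            if key in seen:
                continue
            seen.add(key)
            start = min(r.start for r in combo)
            end = max(r.end for r in combo)
            scores = [r.score for r in combo]
            score = {"sum": sum(scores), "mean": sum(scores) / len(scores),
                     "min": min(scores)}[score_mode]
            occurrences.append(Region(start, end, model.id, score, ".",
                                      children=[r.copy() for r in combo]))
        out[name] = occurrences
    return RegionTrack(motif_track.sequences, out)


def _orientation_ok(r: Region, orient: str) -> bool:
    return orient == "any" or r.strand == orient


def _satisfies(combo: Sequence[Region], model: ModuleModel) -> bool:
    start = min(r.start for r in combo)
    end = max(r.end for r in combo)
    if end - start > model.max_span:
        return False
    in_genomic_order = sorted(combo, key=lambda r: (r.start, r.end))
    if model.ordered and list(combo) != in_genomic_order:
        return False
    # gap constraints apply to genomically adjacent member sites; for an
    # ordered model that pairing coincides with adjacent slots
    for i in range(len(in_genomic_order) - 1):
        lo, hi = model.gaps[i]
        gap = nearest_edge_gap(in_genomic_order[i], in_genomic_order[i + 1])
        if not (lo <= gap <= hi):
            return False
    return True


def interaction_filter(motif_track: RegionTrack,
                       partners: Mapping[str, Set[str]],
                       max_gap: int) -> RegionTrack:
    """Keep only binding sites that have a site for a known interaction
    partner within ``max_gap`` bp (nearest-edge distance; overlapping
    sites count as distance 0).  Survival is judged against the input
    track, so removals do not cascade.
    """
    if max_gap < 0:
        raise CiskitError("max_gap must be >= 0")
    out: Dict[str, List[Region]] = {}
    for name in motif_track.names:
        sites = motif_track[name]
        kept = []
        for r in sites:
            my_partners = partners.get(r.type, set())
            for other in sites:
                if other is r:
                    continue
                if other.type in my_partners and nearest_edge_gap(r, other) <= max_gap:
                    kept.append(r.copy())
                    break
        out[name] = kept
    return RegionTrack(motif_track.sequences, out)


# ----------------------------------------------------------- spec mini-grammar

_SLOTS_RE = re.compile(r"slots\s*=\s*\[(.*?)\]")
_SPAN_RE = re.compile(r"span\s*<=\s*(\d+)")
_GAP_RE = re.compile(r"gap\[(\d+),(\d+)\]\s*=\s*(-?\d+)\.\.(-?\d+|inf)")
_ORIENT_RE = re.compile(r"orient\[(\d+)\]\s*=\s*([+-]|any)")


def module_from_spec(text: str, id: str = "module") -> ModuleModel:
    """Parse the declarative module mini-grammar, e.g.::

        slots=[{M1,M2},{M3}] span<=100 ordered gap[0,1]=5..20 orient[1]=-

    Slot sets are motif-id lists; ``gap[i,j]`` bounds the nearest-edge
    distance between adjacent slots i and j = i+1; ``unordered`` lifts
    the slot-order-along-sequence requirement.
    """
    m = _SLOTS_RE.search(text)
    if not m:
        raise CiskitError("module spec must declare slots=[{...},{...}]")
    slot_text = m.group(1)
    slots = []
    for chunk in re.findall(r"\{([^}]*)\}", slot_text):
        members = {s.strip() for s in chunk.split(",") if s.strip()}
        if not members:
            raise CiskitError("empty slot in module spec")
        slots.append(members)
    if len(slots) < 2:
        raise CiskitError("module spec needs at least 2 slots")

    max_span = _INF
    m = _SPAN_RE.search(text)
    if m:
        max_span = int(m.group(1))
    ordered = "unordered" not in text
    gaps = [(0, _INF)] * (len(slots) - 1)
    for gm in _GAP_RE.finditer(text):
        i, j = int(gm.group(1)), int(gm.group(2))
        if j != i + 1 or not (0 <= i < len(slots) - 1):
            raise CiskitError(f"gap constraint indices ({i},{j}) must be adjacent slots")
        lo = int(gm.group(3))
        hi = _INF if gm.group(4) == "inf" else int(gm.group(4))
        if lo < 0:
            raise CiskitError("gap bounds must be >= 0")
        gaps[i] = (lo, hi)
    orientations = ["any"] * len(slots)
    for om in _ORIENT_RE.finditer(text):
        i = int(om.group(1))
        if not (0 <= i < len(slots)):
            raise CiskitError(f"orientation index {i} out of range")
        orientations[i] = om.group(2)
    return ModuleModel(id, slots, max_span, ordered, orientations, gaps)


def module_to_spec(model: ModuleModel) -> str:
    """Canonical re-serialization of a module model (semantics-preserving
    round trip with :func:`module_from_spec`)."""
    parts = ["slots=[" + ",".join("{" + ",".join(sorted(s)) + "}"
                                  for s in model.slots) + "]"]
    if model.max_span < _INF:
        parts.append(f"span<={model.max_span}")
    parts.append("ordered" if model.ordered else "unordered")
    for i, (lo, hi) in enumerate(model.gaps):
        if (lo, hi) != (0, _INF):
            parts.append(f"gap[{i},{i + 1}]={lo}..{hi if hi < _INF else 'inf'}")
    for i, o in enumerate(model.orientations):
        if o != "any":
            parts.append(f"orient[{i}]={o}")
    return " ".join(parts)
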