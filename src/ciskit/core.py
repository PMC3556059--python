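"""Shared data model for the workbench.

Everything a regulatory-sequence analysis touches is represented by a
small set of data types: genomic sequences, per-position feature tracks
(DNA letters, numeric values, or region lists), motif and module models,
and light-weight container objects (collections, partitions, numeric
maps, text variables).  A :class:`Repository` keeps all live objects
under unique user-chosen names, which is what protocol scripts refer to.

Coordinate convention: all positions are 0-based half-open on the
genomic forward strand.  Strand awareness (reverse complements,
TSS-relative offsets) is applied by the operations that need it, never
baked into storage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger("ciskit")

DNA_ALPHABET = set("ACGTNXacgtnx")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

COMPLEMENT = str.maketrans("ACGTNXacgtnx", "TGCANXtgcanx")

# IUPAC degenerate alphabet: symbol -> set of bases covered
IUPAC_CODES: Dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_IUPAC = {v: k for k, v in IUPAC_CODES.items()}

_IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string (IUPAC N/X preserved)."""
    return s.translate(COMPLEMENT)[::-1]


def is_identifier(name: str) -> bool:
    return bool(_IDENTIFIER_RE.match(name))


class CiskitError(Exception):
    """Base class for all workbench errors."""


@dataclass
class GenomicSequence:
    """A named segment of a genome.

    ``start``/``end`` are genomic base-pair coordinates (0-based
    half-open).  ``tss_offset``, when set, is the position of the
    transcription start site *within* the sequence (it may fall outside
    ``[0, length)`` for windows that do not contain the TSS itself).
    """

    name: str
    chromosome: str = "chr?"
    start: int = 0
    end: int = 0
    strand: str = "+"
    build: str = ""
    tss_offset: Optional[int] = None

    def __post_init__(self):
        if not is_identifier(self.name):
            raise CiskitError(f"invalid sequence name {self.name!r}")
        if self.end <= self.start:
            raise CiskitError(
                f"sequence {self.name}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise CiskitError(f"sequence {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length


class SequenceSet:
    """Ordered collection of :class:`GenomicSequence` with unique names."""

    def __init__(self, sequences: Iterable[GenomicSequence] = ()):
        self._seqs: Dict[str, GenomicSequence] = {}
        for s in sequences:
            self.add(s)

    def add(self, seq: GenomicSequence) -> None:
        if seq.name in self._seqs:
            raise CiskitError(f"duplicate sequence name {seq.name!r}")
        self._seqs[seq.name] = seq

    def __getitem__(self, name: str) -> GenomicSequence:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[GenomicSequence]:
        return iter(self._seqs.values())

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def names(self) -> List[str]:
        return list(self._seqs)

    def __eq__(self, other) -> bool:
        return isinstance(other, SequenceSet) and self._seqs == other._seqs


class _Track:
    """Base for per-sequence feature tracks aligned to a SequenceSet."""

    def __init__(self, sequences: SequenceSet):
        self.sequences = sequences

    @property
    def names(self) -> List[str]:
        return self.sequences.names


class DNATrack(_Track):
    """Per-sequence DNA string, stored in genomic forward orientation."""

    def __init__(self, sequences: SequenceSet, data: Mapping[str, str]):
        super().__init__(sequences)
        self.data: Dict[str, str] = {}
        for seq in sequences:
            if seq.name not in data:
                raise CiskitError(f"DNATrack missing sequence {seq.name!r}")
            s = data[seq.name]
            if len(s) != seq.length:
                raise CiskitError(
                    f"DNATrack {seq.name!r}: string length {len(s)} != sequence length {seq.length}")
            bad = set(s) - DNA_ALPHABET
            if bad:
                raise CiskitError(f"DNATrack {seq.name!r}: illegal characters {sorted(bad)}")
            self.data[seq.name] = s

    def __getitem__(self, name: str) -> str:
        return self.data[name]

    def copy(self) -> "DNATrack":
        return DNATrack(self.sequences, dict(self.data))

    def __eq__(self, other) -> bool:
        return isinstance(other, DNATrack) and self.data == other.data


class NumericTrack(_Track):
    """Per-sequence array of finite float values, one per position."""

    def __init__(self, sequences: SequenceSet, data: Mapping[str, Sequence[float]]):
        super().__init__(sequences)
        self.data: Dict[str, np.ndarray] = {}
        for seq in sequences:
            if seq.name not in data:
                raise CiskitError(f"NumericTrack missing sequence {seq.name!r}")
            arr = np.asarray(data[seq.name], dtype=float)
            if arr.shape != (seq.length,):
                raise CiskitError(
                    f"NumericTrack {seq.name!r}: length {arr.shape} != sequence length {seq.length}")
            if not np.all(np.isfinite(arr)):
                raise CiskitError(f"NumericTrack {seq.name!r}: non-finite values")
            self.data[seq.name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def copy(self) -> "NumericTrack":
        return NumericTrack(self.sequences, {k: v.copy() for k, v in self.data.items()})

    def __eq__(self, other) -> bool:
        return (isinstance(other, NumericTrack)
                and self.data.keys() == other.data.keys()
                and all(np.array_equal(self.data[k], other.data[k]) for k in self.data))


@dataclass
class Region:
    """A typed, scored subsegment of a sequence.

    Coordinates are relative to the sequence start, 0-based half-open.
    ``children`` holds member regions of composite occurrences (e.g. the
    binding sites making up a module occurrence).
    """

    start: int
    end: int
    type: str = ""
    score: float = 0.0
    strand: str = "."
    properties: Dict[str, str] = field(default_factory=dict)
    children: Optional[List["Region"]] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CiskitError(f"region [{self.start},{self.end}): need 0 <= start < end")
        if self.strand not in ("+", "-", "."):
            raise CiskitError(f"region strand must be one of + - . , got {self.strand!r}")
        if self.children:
            for c in self.children:
                if c.start < self.start or c.end > self.end:
                    raise CiskitError("child region extends outside its parent")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self):
        return (self.start, self.end, self.type)

    def copy(self) -> "Region":
        return Region(self.start, self.end, self.type, self.score, self.strand,
                      dict(self.properties),
                      [c.copy() for c in self.children] if self.children else None)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Region):
            return NotImplemented
        return (self.start, self.end, self.type, self.score, self.strand,
                self.properties, self.children or []) == \
               (other.start, other.end, other.type, other.score, other.strand,
                other.properties, other.children or [])


class RegionTrack(_Track):
    """Per-sequence sorted list of regions; regions may overlap."""

    def __init__(self, sequences: SequenceSet,
                 data: Optional[Mapping[str, Iterable[Region]]] = None):
        super().__init__(sequences)
        data = data or {}
        self.data: Dict[str, List[Region]] = {}
        for seq in sequences:
            regions = sorted((r for r in data.get(seq.name, [])), key=Region.sort_key)
            for r in regions:
                if r.end > seq.length:
                    raise CiskitError(
                        f"region [{r.start},{r.end}) exceeds length of sequence {seq.name!r}")
            self.data[seq.name] = regions

    def __getitem__(self, name: str) -> List[Region]:
        return self.data[name]

    def all_regions(self) -> Iterator[tuple]:
        """Yield (sequence name, region) pairs across the track."""
        for name, regions in self.data.items():
            for r in regions:
                yield name, r

    def count(self) -> int:
        return sum(len(v) for v in self.data.values())

    def types(self) -> List[str]:
        return sorted({r.type for _, r in self.all_regions()})

    def copy(self) -> "RegionTrack":
        return RegionTrack(self.sequences,
                           {k: [r.copy() for r in v] for k, v in self.data.items()})

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionTrack) and self.data == other.data


def consensus_from_matrix(matrix: np.ndarray) -> str:
    """Derive an IUPAC consensus from a column-stochastic matrix.

    Per column, the symbol covering exactly the set of bases whose
    frequency is >= 0.25 is used; with four bases summing to one the set
    is never empty, so the rule is total and deterministic.
    """
    out = []
    for col in matrix.T:
        covered = frozenset(BASES[i] for i in range(4) if col[i] >= 0.25)
        out.append(_SET_TO_IUPAC[covered])
    return "".join(out)


class Motif:
    """A binding motif: column-stochastic 4 x w frequency matrix plus
    annotations (transcription factor names, tissues, known interaction
    partners, alternative motif ids)."""

    def __init__(self, id: str, matrix: np.ndarray, consensus: Optional[str] = None,
                 tf_names: Optional[List[str]] = None,
                 organisms: Optional[List[str]] = None,
                 tissues: Optional[List[str]] = None,
                 partners: Optional[List[str]] = None,
                 alternatives: Optional[List[str]] = None):
        self.id = id
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != 4 or matrix.shape[1] < 1:
            raise CiskitError(f"motif {id!r}: matrix must be 4 x w with w >= 1")
        sums = matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise CiskitError(f"motif {id!r}: columns must sum to 1 (got {sums})")
        self.matrix = matrix
        self.consensus = consensus if consensus is not None else consensus_from_matrix(matrix)
        self.tf_names = tf_names or []
        self.organisms = organisms or []
        self.tissues = tissues or []
        self.partners = partners or []
        self.alternatives = alternatives or []

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def __repr__(self) -> str:
        return f"Motif({self.id!r}, w={self.width}, consensus={self.consensus!r})"


class MotifCollectionObj:
    """Ordered motif library keyed by motif id, with a symmetric partner
    relation maintained across members."""

    def __init__(self, motifs: Iterable[Motif] = ()):
        self._motifs: Dict[str, Motif] = {}
        for m in motifs:
            self.add(m)

    def add(self, motif: Motif) -> None:
        if motif.id in self._motifs:
            raise CiskitError(f"duplicate motif id {motif.id!r}")
        self._motifs[motif.id] = motif
        self._symmetrize()

    def _symmetrize(self) -> None:
        for m in self._motifs.values():
            for p in m.partners:
                other = self._motifs.get(p)
                if other is not None and m.id not in other.partners:
                    other.partners.append(m.id)

    def __getitem__(self, mid: str) -> Motif:
        return self._motifs[mid]

    def __contains__(self, mid: str) -> bool:
        return mid in self._motifs

    def __iter__(self) -> Iterator[Motif]:
        return iter(self._motifs.values())

    def __len__(self) -> int:
        return len(self._motifs)

    @property
    def ids(self) -> List[str]:
        return list(self._motifs)

    def partner_map(self) -> Dict[str, set]:
        return {m.id: set(m.partners) for m in self}


@dataclass
class Collection:
    """A named subset of sequences, motifs or modules."""

    member_type: str  # sequence | motif | module
    members: set = field(default_factory=set)

    def __post_init__(self):
        self.members = set(self.members)

    def __contains__(self, name: str) -> bool:
        return name in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))


@dataclass
class Partition:
    """Division of members into non-overlapping clusters; members may be
    left unassigned."""

    member_type: str
    assignment: Dict[str, str] = field(default_factory=dict)

    def cluster(self, label: str) -> Collection:
        return Collection(self.member_type,
                          {m for m, c in self.assignment.items() if c == label})

    @property
    def clusters(self) -> List[str]:
        return sorted(set(self.assignment.values()))


@dataclass
class NumericMap:
    """Member -> value map with a default for absent members."""

    member_type: str
    values: Dict[str, float] = field(default_factory=dict)
    default: float = 0.0

    def __post_init__(self):
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise CiskitError(f"NumericMap value for {k!r} not finite")

    def __getitem__(self, member: str) -> float:
        return self.values.get(member, self.default)

    def __contains__(self, member: str) -> bool:
        return member in self.values

    def items(self):
        return self.values.items()


@dataclass
class TextVariable:
    text: str = ""


class Repository:
    """In-memory store of named data objects.

    Names follow identifier grammar (letters, digits, underscore, not
    starting with a digit).  Re-assignment replaces the prior object; a
    type change is allowed but logged, matching the workbench convention
    that storing under a new name is the caller's choice.
    """

    def __init__(self):
        self._objects: Dict[str, object] = {}

    def put(self, name: str, obj: object) -> object:
        if not is_identifier(name):
            raise CiskitError(f"invalid data object name {name!r}")
        if name in self._objects:
            old, new = type(self._objects[name]).__name__, type(obj).__name__
            if old != new:
                logger.warning("repository: %r reassigned from %s to %s", name, old, new)
            else:
                logger.warning("repository: %r overwritten", name)
        self._objects[name] = obj
        return obj

    def get(self, name: str) -> object:
        if name not in self._objects:
            raise CiskitError(f"no data object named {name!r}")
        return self._objects[name]

    def __contains__(self, name: str) -> bool:
        return name in self._objects

    def __delitem__(self, name: str) -> None:
        del self._objects[name]

    @property
    def names(self) -> List[str]:
        return list(self._objects)

    def copy(self) -> "Repository":
        r = Repository()
        r._objects = dict(self._objects)
        return r
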