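"""Reading and writing the standard text formats the workbench touches.

Formats: FASTA (DNA tracks, via Biopython), GFF3 and BED6 (region
tracks), fixed-step WIG and bedGraph (numeric tracks), JASPAR PFM /
TRANSFAC / MEME-minimal motif libraries (via Bio.motifs), the MEME PSP
positional-priors dialect, and a tab-separated gene annotation table.

Conventions: GFF is 1-based inclusive on disk and 0-based half-open in
memory; BED and bedGraph are 0-based half-open in both.  Region tracks
round-trip losslessly through GFF: the region type goes to the ``Name``
attribute, the property map to one attribute each, and module children
to ``Parent``-linked child lines.  All writers are deterministic:
identical input produces byte-identical output.

Sequence-to-record matching uses exact chromosome label equality plus
coordinate overlap; records outside every sequence are dropped (count
logged), records partially overlapping are clipped.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (CiskitError, DNATrack, GenomicSequence, Motif,
                   MotifCollectionObj, NumericTrack, Region, RegionTrack,
                   SequenceSet)
from .motifs import normalize_matrix

logger = logging.getLogger("ciskit")


# ----------------------------------------------------------------- sequences

def sequences_from_coordinates(specs: Iterable[tuple]) -> SequenceSet:
    """Build a sequence set from (name, chrom, start, end, strand[, build])
    tuples; duplicate names or empty windows are errors."""
    out = SequenceSet()
    for spec in specs:
        name, chrom, start, end, strand = spec[:5]
        build = spec[5] if len(spec) > 5 else ""
        out.add(GenomicSequence(name, chrom, int(start), int(end), strand, build))
    return out


class GeneAnnotationTable:
    """Rows of (gene id, chromosome, strand, TSS, TES) genomic positions."""

    COLUMNS = ["gene", "chrom", "strand", "tss", "tes"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise CiskitError(f"gene annotation missing columns {missing}")
        if frame["gene"].duplicated().any():
            raise CiskitError("gene ids must be unique")
        if (frame[["tss", "tes"]] < 0).any().any():
            raise CiskitError("gene positions must be non-negative")
        self.frame = frame.set_index("gene", drop=False)

    @classmethod
    def read(cls, path) -> "GeneAnnotationTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __contains__(self, gene: str) -> bool:
        return gene in self.frame.index

    def row(self, gene: str):
        return self.frame.loc[gene]


def sequences_from_genes(genes: Sequence[str], annotation: GeneAnnotationTable,
                         anchor: str = "TSS", upstream: int = 2000,
                         downstream: int = 200, build: str = "") -> SequenceSet:
    """Strand-aware promoter windows around gene anchors.

    For a plus-strand gene the window is [anchor - upstream, anchor +
    downstream); mirrored for minus-strand genes.  Windows reaching below
    position 0 are clipped with a warning; unknown gene ids are reported
    and skipped.  Defaults give the classic 2000 bp upstream / 200 bp
    downstream promoter region.
    """
    if anchor not in ("TSS", "TES"):
        raise CiskitError("anchor must be 'TSS' or 'TES'")
    if upstream == 0 and downstream == 0:
        raise CiskitError("empty window: upstream and downstream both 0")
    out = SequenceSet()
    for gene in genes:
        if gene not in annotation:
            logger.warning("gene %r not found in annotation; skipped", gene)
            continue
        row = annotation.row(gene)
        pos = int(row["tss"] if anchor == "TSS" else row["tes"])
        strand = row["strand"]
        if strand == "+":
            start, end = pos - upstream, pos + downstream
        else:
            start, end = pos - downstream, pos + upstream
        if start < 0:
            logger.warning("window for %r clipped at chromosome start", gene)
            start = 0
        seq = GenomicSequence(gene, str(row["chrom"]), start, end, strand, build,
                              tss_offset=(int(row["tss"]) - start))
        out.add(seq)
    return out


# -------------------------------------------------------------------- tracks

def read_track(path, format: str, sequences: SequenceSet):
    """Read a file into a feature track aligned to the sequence set."""
    if format == "fasta":
        return _read_fasta(path, sequences)
    if format == "gff":
        return _read_gff(path, sequences)
    if format == "bed":
        return _read_bed(path, sequences)
    if format == "wig":
        return _read_wig(path, sequences)
    if format == "bedgraph":
        return _read_bedgraph(path, sequences)
    raise CiskitError(f"unknown track format {format!r}")


def write_track(track, path, format: str) -> None:
    """Write a track; the format must match the track type
    (fasta <-> DNA, gff/bed <-> regions, wig <-> numeric)."""
    if format == "fasta":
        if not isinstance(track, DNATrack):
            raise CiskitError("fasta requires a DNA track")
        _write_fasta(track, path)
    elif format == "gff":
        if not isinstance(track, RegionTrack):
            raise CiskitError("gff requires a region track")
        _write_gff(track, path)
    elif format == "bed":
        if not isinstance(track, RegionTrack):
            raise CiskitError("bed requires a region track")
        _write_bed(track, path)
    elif format == "wig":
        if not isinstance(track, NumericTrack):
            raise CiskitError("wig requires a numeric track")
        _write_wig(track, path)
    else:
        raise CiskitError(f"unknown track format {format!r}")


def _read_fasta(path, sequences: SequenceSet) -> DNATrack:
    data = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in sequences:
            logger.warning("FASTA record %r matches no sequence; dropped", rec.id)
            continue
        s = str(rec.seq)
        if len(s) != sequences[rec.id].length:
            raise CiskitError(
                f"FASTA record {rec.id!r}: length {len(s)} != sequence length "
                f"{sequences[rec.id].length}")
        data[rec.id] = s
    return DNATrack(sequences, data)


def _write_fasta(track: DNATrack, path) -> None:
    records = [SeqRecord(Seq(track[name]), id=name, description="")
               for name in track.names]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _overlapping_sequences(sequences: SequenceSet, chrom: str,
                           gstart: int, gend: int):
    for seq in sequences:
        if seq.chromosome == chrom and gstart < seq.end and seq.start < gend:
            yield seq


_RESERVED_GFF_ATTRS = ("ID", "Name", "Parent")


def _format_score(x: float) -> str:
    return repr(float(x))


def _read_gff(path, sequences: SequenceSet) -> RegionTrack:
    data: Dict[str, List[Region]] = {name: [] for name in sequences.names}
    pending_children: List[Tuple[str, str, Region]] = []  # (seq, parent id, child)
    by_id: Dict[Tuple[str, str], Region] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise CiskitError(f"{path}: malformed GFF record at line {lineno}")
            chrom, _src, rtype, start, end, score, strand, _frame, attrs = parts
            try:
                gstart, gend = int(start) - 1, int(end)  # 1-based inclusive on disk
            except ValueError:
                raise CiskitError(f"{path}: bad coordinates at line {lineno}")
            attrmap = _parse_gff_attributes(attrs)
            rtype = attrmap.pop("Name", rtype)
            rid = attrmap.pop("ID", None)
            parent = attrmap.pop("Parent", None)
            matched = False
            for seq in _overlapping_sequences(sequences, chrom, gstart, gend):
                matched = True
                rel_start = max(gstart, seq.start) - seq.start
                rel_end = min(gend, seq.end) - seq.start
                region = Region(rel_start, rel_end, rtype,
                                float(score) if score != "." else 0.0,
                                strand if strand in "+-." else ".",
                                dict(attrmap))
                if parent is not None:
                    pending_children.append((seq.name, parent, region))
                else:
                    data[seq.name].append(region)
                    if rid is not None:
                        by_id[(seq.name, rid)] = region
            if not matched:
                dropped += 1
    for seq_name, parent, child in pending_children:
        parent_region = by_id.get((seq_name, parent))
        if parent_region is None:
            raise CiskitError(f"{path}: child refers to unknown parent {parent!r}")
        if parent_region.children is None:
            parent_region.children = []
        parent_region.children.append(child)
    if dropped:
        logger.warning("%s: %d records outside all sequences dropped", path, dropped)
    return RegionTrack(sequences, data)


def _parse_gff_attributes(text: str) -> Dict[str, str]:
    out = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise CiskitError(f"malformed GFF attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def _write_gff(track: RegionTrack, path) -> None:
    lines = ["##gff-version 3"]
    counter = 0
    for seq in track.sequences:
        for r in track[seq.name]:
            counter += 1
            rid = f"r{counter}"
            lines.append(_gff_line(seq, r, rid, parent=None))
            for child in (r.children or []):
                counter += 1
                lines.append(_gff_line(seq, child, f"r{counter}", parent=rid))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff_line(seq: GenomicSequence, r: Region, rid: str, parent: Optional[str]) -> str:
    attrs = [f"ID={rid}", f"Name={r.type}"]
    if parent is not None:
        attrs.append(f"Parent={parent}")
    for k in sorted(r.properties):
        if k in _RESERVED_GFF_ATTRS:
            raise CiskitError(f"region property name {k!r} is reserved in GFF")
        attrs.append(f"{k}={r.properties[k]}")
    return "\t".join([
        seq.chromosome, "ciskit", r.type or "region",
        str(seq.start + r.start + 1), str(seq.start + r.end),
        _format_score(r.score), r.strand, ".", ";".join(attrs)])


def _read_bed(path, sequences: SequenceSet) -> RegionTrack:
    data: Dict[str, List[Region]] = {name: [] for name in sequences.names}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CiskitError(f"{path}: malformed BED record at line {lineno}")
            chrom = parts[0]
            gstart, gend = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "region"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-." else "."
            matched = False
            for seq in _overlapping_sequences(sequences, chrom, gstart, gend):
                matched = True
                data[seq.name].append(Region(
                    max(gstart, seq.start) - seq.start,
                    min(gend, seq.end) - seq.start, name, score, strand))
            if not matched:
                dropped += 1
    if dropped:
        logger.warning("%s: %d records outside all sequences dropped", path, dropped)
    return RegionTrack(sequences, data)


def _write_bed(track: RegionTrack, path) -> None:
    lines = []
    for seq in track.sequences:
        for r in track[seq.name]:
            lines.append("\t".join([
                seq.chromosome, str(seq.start + r.start), str(seq.start + r.end),
                r.type or "region", _format_score(r.score), r.strand]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def _read_wig(path, sequences: SequenceSet) -> NumericTrack:
    data = {name: np.zeros(sequences[name].length) for name in sequences.names}
    chrom, gpos, step = None, 0, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                gpos = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                continue
            if chrom is None:
                raise CiskitError(f"{path}: data before fixedStep header (line {lineno})")
            try:
                value = float(line)
            except ValueError:
                raise CiskitError(f"{path}: bad value at line {lineno}")
            for seq in _overlapping_sequences(sequences, chrom, gpos, gpos + 1):
                data[seq.name][gpos - seq.start] = value
            gpos += step
    return NumericTrack(sequences, data)


def _write_wig(track: NumericTrack, path) -> None:
    lines = []
    for seq in track.sequences:
        lines.append(f"fixedStep chrom={seq.chromosome} start={seq.start + 1} step=1")
        lines.extend(repr(float(v)) for v in track[seq.name])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_bedgraph(path, sequences: SequenceSet) -> NumericTrack:
    data = {name: np.zeros(sequences[name].length) for name in sequences.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CiskitError(f"{path}: malformed bedGraph record at line {lineno}")
            chrom, gstart, gend, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            for seq in _overlapping_sequences(sequences, chrom, gstart, gend):
                a = max(gstart, seq.start) - seq.start
                b = min(gend, seq.end) - seq.start
                data[seq.name][a:b] = value
    return NumericTrack(sequences, data)


# -------------------------------------------------------------------- motifs

def read_motifs(path, format: str) -> MotifCollectionObj:
    """Read a motif library (JASPAR PFM, TRANSFAC matrix blocks, or MEME
    minimal format) into column-stochastic motifs with the documented
    pseudocounts applied."""
    dialect = {"jaspar": "jaspar", "transfac": "TRANSFAC", "meme": "minimal"}.get(format)
    if dialect is None:
        raise CiskitError(f"unknown motif format {format!r}")
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, dialect)
        except Exception as exc:  # biopython raises assorted exceptions
            raise CiskitError(f"{path}: cannot parse as {format}: {exc}") from exc
    out = MotifCollectionObj()
    for i, m in enumerate(parsed):
        mid = (getattr(m, "matrix_id", None) or m.name
               or (m.get("ID") if isinstance(m, dict) else None)
               or (m.get("AC") if isinstance(m, dict) else None)
               or f"motif_{i + 1}")
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        if np.any(counts.sum(axis=0) == 0):
            raise CiskitError(f"{path}: motif {mid!r} has a zero-sum column")
        kind = "probabilities" if format == "meme" else "counts"
        out.add(Motif(str(mid).replace(" ", "_"), normalize_matrix(counts, kind)))
    return out


# -------------------------------------------------------------------- priors

def export_priors(priors: NumericTrack, path, format: str = "psp") -> None:
    """Write a priors track in the MEME PSP dialect: FASTA-like records
    of whitespace-separated per-position values, 6 significant digits."""
    if format != "psp":
        raise CiskitError(f"unknown priors format {format!r}")
    lines = []
    for name in priors.names:
        v = priors[name]
        if np.any(v < 0):
            raise CiskitError(f"negative prior value in sequence {name!r}")
        lines.append(f">{name}")
        lines.append(" ".join(f"{x:.6g}" for x in v))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_priors(path, sequences: SequenceSet) -> NumericTrack:
    """Internal reader for the PSP dialect (round-trip check for
    :func:`export_priors`)."""
    data: Dict[str, np.ndarray] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    data[name] = np.array([float(x) for x in " ".join(chunks).split()])
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        data[name] = np.array([float(x) for x in " ".join(chunks).split()])
    return NumericTrack(sequences, data)
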