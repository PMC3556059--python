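"""Statistical analyses over motif tracks and benchmark metrics.

The analyses answer the standard questions of a regulatory-sequence
study: how often does each motif occur and in how many sequences; is it
overrepresented relative to a background expectation (exact binomial
test with Bonferroni correction); does it prefer one sequence group over
another (Fisher's exact test); do its sites cluster positionally
(kurtosis of TSS-relative midpoints); how conserved are its sites on
average; and how do several such properties combine into one ranking
(rank sum).  Results are typed tables that can be collated into
meta-analyses, converted to numeric maps / collections, and rendered as
HTML or raw text.

Benchmark metrics compare a predicted site track against an answer key
at nucleotide level (Sn, Sp, PPV, Acc, PC, ASP, F, Matthews CC) and at
site level (sSn: fraction of target sites hit by a prediction covering
at least a given fraction of the target's length, 25% by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binom, fisher_exact, rankdata

from .core import (CiskitError, Collection, NumericMap, NumericTrack, Region,
                   RegionTrack)

logger = logging.getLogger("ciskit")

COLUMN_TYPES = ("number", "text", "histogram", "class")


class AnalysisResult:
    """A typed result table keyed by member (motif / sequence / module).

    Columns carry a declared type; numeric columns can be extracted as
    :class:`~ciskit.core.NumericMap` and boolean predicates on them as
    :class:`~ciskit.core.Collection`, so analysis output feeds back into
    further operations.
    """

    def __init__(self, name: str, table: pd.DataFrame,
                 column_types: Mapping[str, str], provenance: str = "",
                 extras: Optional[dict] = None):
        for col in table.columns:
            if col not in column_types:
                raise CiskitError(f"column {col!r} missing a declared type")
            if column_types[col] not in COLUMN_TYPES:
                raise CiskitError(f"bad column type {column_types[col]!r}")
        if table.index.duplicated().any():
            raise CiskitError("result keys must be unique")
        self.name = name
        self.table = table
        self.column_types = dict(column_types)
        self.provenance = provenance
        self.extras = extras or {}

    @property
    def members(self) -> List[str]:
        return list(self.table.index)

    def to_numeric_map(self, column: str, member_type: str = "motif",
                       default: float = 0.0) -> NumericMap:
        if self.column_types.get(column) != "number":
            raise CiskitError(f"column {column!r} is not numeric")
        values = {k: float(v) for k, v in self.table[column].items()
                  if v is not None and np.isfinite(v)}
        return NumericMap(member_type, values, default)

    def to_collection(self, column: str, op: str, value,
                      member_type: str = "motif") -> Collection:
        import operator
        ops = {"<": operator.lt, "<=": operator.le, ">": operator.gt,
               ">=": operator.ge, "=": operator.eq, "==": operator.eq,
               "!=": operator.ne}
        col = self.table[column]
        members = {k for k, v in col.items()
                   if v is not None and not (isinstance(v, float) and math.isnan(v))
                   and ops[op](v, value)}
        return Collection(member_type, members)


# ------------------------------------------------------------------ counting

def count_motif_occurrences(motif_track: RegionTrack,
                            sequences: Optional[Collection] = None) -> AnalysisResult:
    """Per motif: total number of sites and support (number of sequences
    with at least one site)."""
    names = list(sequences) if sequences is not None else motif_track.names
    totals: Dict[str, int] = {}
    support: Dict[str, set] = {}
    for name in names:
        for r in motif_track[name]:
            totals[r.type] = totals.get(r.type, 0) + 1
            support.setdefault(r.type, set()).add(name)
    keys = sorted(totals)
    table = pd.DataFrame({
        "total": [totals[k] for k in keys],
        "support": [len(support[k]) for k in keys],
    }, index=pd.Index(keys, name="motif"))
    return AnalysisResult("count motif occurrences", table,
                          {"total": "number", "support": "number"},
                          provenance=f"count_motif_occurrences over {len(names)} sequences")


def overrepresentation(counts: AnalysisResult, expected_freq: NumericMap,
                       total_bp: int, alpha: float = 0.05,
                       correction: str = "bonferroni") -> AnalysisResult:
    """Exact binomial overrepresentation test per motif.

    With k observed sites and an expected per-bp site frequency f (from
    control sequences), p = P(X >= k) for X ~ Binomial(total_bp, f),
    computed by the exact survival function.  The significance flag uses
    the Bonferroni-corrected threshold alpha / m over the m motifs
    tested (or plain alpha with ``correction='none'``).
    """
    if total_bp <= 0:
        raise CiskitError("total_bp must be positive")
    if correction not in ("bonferroni", "none"):
        raise CiskitError(f"unknown correction {correction!r}")
    m = len(counts.members)
    threshold = alpha / m if (correction == "bonferroni" and m) else alpha
    pvals, sig = [], []
    for motif in counts.members:
        f = expected_freq[motif]
        if f < 0 or f > 1:
            raise CiskitError(f"expected frequency for {motif!r} outside [0, 1]")
        k = int(counts.table.loc[motif, "total"])
        p = float(binom.sf(k - 1, total_bp, f)) if k > 0 else 1.0
        pvals.append(p)
        sig.append(p <= threshold)
    table = counts.table.copy()
    table["p_value"] = pvals
    table["significant"] = sig
    types = dict(counts.column_types, p_value="number", significant="class")
    return AnalysisResult("motif overrepresentation", table, types,
                          provenance=(f"binomial test, n={total_bp} bp, alpha={alpha}, "
                                      f"{correction} threshold={threshold:.3g}, m={m}"),
                          extras={"corrected_threshold": threshold, "m": m})


def group_comparison(motif_track: RegionTrack, groupA: Collection,
                     groupB: Collection, alpha: float = 0.05) -> AnalysisResult:
    """Compare per-motif site counts between two disjoint sequence
    groups with a two-sided Fisher exact test on the 2x2 table of
    (sites, non-site bp) per group.

    Class labels: A = overrepresented in group A at the Bonferroni-
    corrected threshold, B = in group A at nominal alpha only, D =
    overrepresented in group B at nominal alpha or better, C = neither.
    """
    overlap = set(groupA.members) & set(groupB.members)
    if overlap:
        raise CiskitError(f"groups overlap: {sorted(overlap)}")
    if not groupA.members or not groupB.members:
        raise CiskitError("both groups must be non-empty")
    bpA = sum(motif_track.sequences[n].length for n in groupA)
    bpB = sum(motif_track.sequences[n].length for n in groupB)
    motifs = motif_track.types()
    m = len(motifs)
    rows = []
    for motif in motifs:
        kA = sum(1 for n in groupA for r in motif_track[n] if r.type == motif)
        kB = sum(1 for n in groupB for r in motif_track[n] if r.type == motif)
        _, p = fisher_exact([[kA, max(bpA - kA, 0)], [kB, max(bpB - kB, 0)]],
                            alternative="two-sided")
        rateA, rateB = kA / bpA, kB / bpB
        if rateA > rateB and p <= alpha / max(m, 1):
            cls = "A"
        elif rateA > rateB and p <= alpha:
            cls = "B"
        elif rateB > rateA and p <= alpha:
            cls = "D"
        else:
            cls = "C"
        rows.append((motif, kA, kB, p, cls))
    table = pd.DataFrame(rows, columns=["motif", "sites_A", "sites_B",
                                        "p_value", "group"]).set_index("motif")
    return AnalysisResult(
        "group comparison", table,
        {"sites_A": "number", "sites_B": "number", "p_value": "number",
         "group": "class"},
        provenance=f"Fisher exact, |A|={len(groupA)}, |B|={len(groupB)}, alpha={alpha}")


# ---------------------------------------------------------------- positional

def _relative_midpoint(r: Region, seq, anchor: str) -> int:
    mid = r.midpoint
    if anchor == "tss":
        if seq.tss_offset is None:
            raise CiskitError(f"sequence {seq.name!r} has no TSS offset")
        return mid - seq.tss_offset if seq.strand == "+" else seq.tss_offset - mid
    if anchor == "sequence_end":
        return mid - seq.length
    raise CiskitError(f"unknown anchor {anchor!r}")


def positional_distribution(motif_track: RegionTrack, anchor: str = "tss",
                            bin_size: int = 50,
                            kurtosis_kind: str = "pearson") -> AnalysisResult:
    """Positional distribution of site midpoints relative to an anchor.

    Midpoints are strand-aware (upstream of the TSS is negative).  Per
    motif the result holds a histogram over a common bin grid and the
    kurtosis m4/m2^2 of the midpoints (population moments; Pearson
    convention, normal ~ 3; ``kurtosis_kind='excess'`` subtracts 3).
    Motifs with fewer than 4 sites get a blank kurtosis.
    """
    if bin_size < 1:
        raise CiskitError("bin_size must be >= 1")
    positions: Dict[str, List[int]] = {}
    for name in motif_track.names:
        seq = motif_track.sequences[name]
        for r in motif_track[name]:
            positions.setdefault(r.type, []).append(
                _relative_midpoint(r, seq, anchor))
    if positions:
        allpos = [p for ps in positions.values() for p in ps]
        lo = (min(allpos) // bin_size) * bin_size
        hi = ((max(allpos) // bin_size) + 1) * bin_size
        edges = np.arange(lo, hi + 1, bin_size)
    else:
        edges = np.array([0, bin_size])
    rows = []
    for motif in sorted(positions):
        pts = np.array(positions[motif], dtype=float)
        hist, _ = np.histogram(pts, bins=edges)
        if pts.size < 4:
            kurt = float("nan")
        else:
            m2 = float(np.mean((pts - pts.mean()) ** 2))
            if m2 == 0:
                logger.warning("motif %s: all sites at one position; kurtosis undefined",
                               motif)
                kurt = float("nan")
            else:
                m4 = float(np.mean((pts - pts.mean()) ** 4))
                kurt = m4 / m2 ** 2
                if kurtosis_kind == "excess":
                    kurt -= 3.0
        rows.append((motif, kurt, ",".join(str(int(h)) for h in hist)))
    table = pd.DataFrame(rows, columns=["motif", "kurtosis", "histogram"]
                         ).set_index("motif")
    return AnalysisResult("positional distribution", table,
                          {"kurtosis": "number", "histogram": "histogram"},
                          provenance=f"anchor={anchor}, bin_size={bin_size}",
                          extras={"bin_edges": edges.tolist()})


def sites_vs_numeric(motif_track: RegionTrack, feature: NumericTrack,
                     stat: str = "mean") -> AnalysisResult:
    """Per motif, the mean of a numeric feature over all positions of
    all its sites (position-weighted, so longer sites weigh more)."""
    if stat != "mean":
        raise CiskitError(f"unknown statistic {stat!r}")
    sums: Dict[str, float] = {}
    lens: Dict[str, int] = {}
    for name in motif_track.names:
        v = feature[name]
        for r in motif_track[name]:
            sums[r.type] = sums.get(r.type, 0.0) + float(v[r.start:r.end].sum())
            lens[r.type] = lens.get(r.type, 0) + r.length
    keys = sorted(sums)
    table = pd.DataFrame({"mean": [sums[k] / lens[k] if lens[k] else float("nan")
                                   for k in keys]},
                         index=pd.Index(keys, name="motif"))
    return AnalysisResult("sites vs numeric feature", table, {"mean": "number"},
                          provenance=f"position-weighted {stat}")


# ------------------------------------------------------------------ rank sum

def rank_sum(maps: Sequence[Tuple[NumericMap, str]]) -> NumericMap:
    """Combine several per-member scores into one by summing ranks.

    Each map contributes ranks 1..n in its stated direction ('ascending'
    ranks small values best, 'descending' large values best) with
    midranks for ties; members absent from a map (blanks) share the
    trailing midrank.  Lower rank sum = better.
    """
    if len(maps) < 2:
        raise CiskitError("rank_sum needs at least 2 maps")
    members = sorted(set().union(*[set(m.values) for m, _ in maps]))
    common = set.intersection(*[set(m.values) for m, _ in maps])
    if not common:
        raise CiskitError("rank_sum maps share no members")
    total = np.zeros(len(members))
    n = len(members)
    for nmap, direction in maps:
        if direction not in ("ascending", "descending"):
            raise CiskitError(f"unknown direction {direction!r}")
        present = [i for i, m in enumerate(members)
                   if m in nmap and np.isfinite(nmap[m])]
        values = np.array([nmap[members[i]] for i in present])
        if direction == "descending":
            values = -values
        ranks = rankdata(values)
        col = np.full(n, (len(present) + 1 + n) / 2.0)  # blanks share tail midrank
        for i, r in zip(present, ranks):
            col[i] = r
        total += col
    return NumericMap(maps[0][0].member_type,
                      {m: float(t) for m, t in zip(members, total)},
                      default=float(2 * n))


# ----------------------------------------------------------------- benchmark

@dataclass
class BenchmarkStats:
    """Nucleotide-level confusion counts and the derived statistics,
    plus site-level sensitivity.  Zero-denominator rates are defined as
    0 so perfect-absence cases stay well-defined."""

    TP: int
    FP: int
    TN: int
    FN: int
    sSn: float = 0.0

    @staticmethod
    def _safe(num: float, den: float) -> float:
        return num / den if den else 0.0

    @property
    def Sn(self) -> float:
        return self._safe(self.TP, self.TP + self.FN)

    @property
    def Sp(self) -> float:
        return self._safe(self.TN, self.TN + self.FP)

    @property
    def PPV(self) -> float:
        return self._safe(self.TP, self.TP + self.FP)

    @property
    def Acc(self) -> float:
        return self._safe(self.TP + self.TN, self.TP + self.FP + self.TN + self.FN)

    @property
    def PC(self) -> float:
        return self._safe(self.TP, self.TP + self.FP + self.FN)

    @property
    def ASP(self) -> float:
        return (self.Sn + self.PPV) / 2.0

    @property
    def F(self) -> float:
        return self._safe(2 * self.Sn * self.PPV, self.Sn + self.PPV)

    @property
    def CC(self) -> float:
        num = self.TP * self.TN - self.FP * self.FN
        den = math.sqrt(float(self.TP + self.FP) * (self.TP + self.FN)
                        * (self.TN + self.FP) * (self.TN + self.FN))
        return num / den if den else 0.0

    def as_dict(self) -> Dict[str, float]:
        return {"TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
                "Sn": self.Sn, "Sp": self.Sp, "PPV": self.PPV, "Acc": self.Acc,
                "PC": self.PC, "ASP": self.ASP, "F": self.F, "CC": self.CC,
                "sSn": self.sSn}


def benchmark_stats(predicted: RegionTrack, answer: RegionTrack,
                    site_overlap_fraction: float = 0.25) -> BenchmarkStats:
    """Compare predicted sites against an answer key.

    Nucleotide counts label each position predicted-positive iff covered
    by >= 1 predicted region (likewise answer-positive); sSn counts a
    target site as found when some single predicted site overlaps at
    least ``site_overlap_fraction`` of the target's length.
    """
    tp = fp = tn = fn = 0
    hit_targets = total_targets = 0
    for seq in predicted.sequences:
        pred_cov = np.zeros(seq.length, dtype=bool)
        ans_cov = np.zeros(seq.length, dtype=bool)
        for r in predicted[seq.name]:
            pred_cov[r.start:r.end] = True
        for r in answer[seq.name]:
            ans_cov[r.start:r.end] = True
        tp += int(np.sum(pred_cov & ans_cov))
        fp += int(np.sum(pred_cov & ~ans_cov))
        fn += int(np.sum(~pred_cov & ans_cov))
        tn += int(np.sum(~pred_cov & ~ans_cov))
        for target in answer[seq.name]:
            total_targets += 1
            need = site_overlap_fraction * target.length
            for p in predicted[seq.name]:
                overlap = min(p.end, target.end) - max(p.start, target.start)
                if overlap >= need and overlap > 0:
                    hit_targets += 1
                    break
    ssn = hit_targets / total_targets if total_targets else 0.0
    return BenchmarkStats(tp, fp, tn, fn, sSn=ssn)


# ------------------------------------------------------------------- collate

def collate(analyses: Sequence[Tuple[AnalysisResult, Sequence[str]]],
            name: str = "meta-analysis",
            sort_by: Optional[Sequence[Tuple[str, str]]] = None) -> AnalysisResult:
    """Column-join selected columns of several analyses into one
    meta-analysis table; optionally sort by the rank sum of named
    numeric columns (column, direction) with blanks ranked last."""
    if not analyses:
        raise CiskitError("nothing to collate")
    frames = []
    types: Dict[str, str] = {}
    for result, columns in analyses:
        cols = list(columns)
        sub = result.table[cols].copy()
        renames = {}
        for c in cols:
            label = c
            if label in types:
                label = f"{c}_{result.name.replace(' ', '_')}"
                logger.warning("collate: duplicate column %r renamed to %r", c, label)
                renames[c] = label
            types[label] = result.column_types[c]
        sub = sub.rename(columns=renames)
        frames.append(sub)
    table = pd.concat(frames, axis=1, join="outer")
    table.index.name = analyses[0][0].table.index.name or "member"
    if sort_by:
        maps = []
        for col, direction in sort_by:
            values = {k: float(v) for k, v in table[col].items()
                      if v is not None and np.isfinite(v)}
            maps.append((NumericMap("member", values), direction))
        combined = rank_sum(maps)
        table = table.loc[sorted(table.index, key=lambda k: (combined[k], k))]
    provenance = "collate(" + ", ".join(r.name for r, _ in analyses) + ")"
    return AnalysisResult(name, table, types, provenance=provenance)


# ----------------------------------------------------------------- rendering

def _format_cell(value, ctype: str) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if ctype == "number":
        if isinstance(value, (bool, np.bool_)):
            return "yes" if value else "no"
        return f"{value:.6g}"
    if ctype == "class" and isinstance(value, (bool, np.bool_)):
        return "yes" if value else "no"
    return str(value)


def _histogram_svg(counts: List[int], width: int = 120, height: int = 32) -> str:
    if not counts or max(counts) == 0:
        return f'<svg width="{width}" height="{height}"></svg>'
    peak = max(counts)
    bar_w = width / len(counts)
    bars = []
    for i, c in enumerate(counts):
        h = round(height * c / peak, 2)
        bars.append(f'<rect x="{round(i * bar_w, 2)}" y="{round(height - h, 2)}" '
                    f'width="{round(bar_w, 2)}" height="{h}" fill="#4878a8"/>')
    return f'<svg width="{width}" height="{height}">' + "".join(bars) + "</svg>"


def motif_logo_svg(matrix: np.ndarray, width_per_col: int = 12,
                   height: int = 30) -> str:
    """Minimal deterministic sequence-logo SVG: letters stacked by
    information content per column."""
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    bases = "ACGT"
    w = matrix.shape[1]
    parts = [f'<svg width="{w * width_per_col}" height="{height}">']
    for j in range(w):
        col = matrix[:, j]
        info = 2.0 + float(np.sum(col * np.log2(np.maximum(col, 1e-12))))
        y = float(height)
        order = sorted(range(4), key=lambda i: (col[i], bases[i]))
        for i in order:
            h = round(height * col[i] * info / 2.0, 2)
            if h <= 0.2:
                continue
            y -= h
            parts.append(
                f'<text x="{j * width_per_col}" y="{round(y + h, 2)}" '
                f'font-family="monospace" font-size="{h}px" '
                f'fill="{colors[bases[i]]}">{bases[i]}</text>')
    parts.append("</svg>")
    return "".join(parts)


def render_result(result: AnalysisResult, format: str = "raw",
                  motifs=None) -> str:
    """Render a result table as raw text (UTF-8 TSV, histograms as
    comma-joined bin counts) or a self-contained HTML document with
    embedded SVG histograms and, when a motif library is supplied, a
    logo per motif row.  Output bytes are deterministic for fixed input.
    """
    if format == "raw":
        key = result.table.index.name or "member"
        lines = ["\t".join([key] + list(result.table.columns))]
        for member, row in result.table.iterrows():
            cells = [str(member)]
            for col in result.table.columns:
                cells.append(_format_cell(row[col], result.column_types[col]))
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"
    if format != "html":
        raise CiskitError(f"unknown output format {format!r}")

    key = result.table.index.name or "member"
    head = (f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{result.name}</title><style>"
            "table{border-collapse:collapse}td,th{border:1px solid #999;"
            "padding:2px 6px;font:12px sans-serif}.significant{background:#fbb}"
            "</style></head><body>")
    rows = [head, f"<h1>{result.name}</h1>",
            f"<p>{result.provenance}</p>", "<table>"]
    headers = [key] + (["logo"] if motifs is not None else []) + list(result.table.columns)
    rows.append("<tr>" + "".join(f"<th>{h}</th>" for h in headers) + "</tr>")
    for member, row in result.table.iterrows():
        cells = [f"<td>{member}</td>"]
        if motifs is not None:
            logo = motif_logo_svg(motifs[member].matrix) if member in motifs else ""
            cells.append(f"<td>{logo}</td>")
        for col in result.table.columns:
            ctype = result.column_types[col]
            value = row[col]
            if ctype == "histogram":
                counts = [int(x) for x in str(value).split(",")] if value else []
                cells.append(f"<td>{_histogram_svg(counts)}</td>")
            else:
                text = _format_cell(value, ctype)
                css = ""
                if col == "p_value" and "significant" in result.table.columns \
                        and bool(row.get("significant")):
                    css = " class='significant'"
                cells.append(f"<td{css}>{text}</td>")
        rows.append("<tr>" + "".join(cells) + "</tr>")
    rows.append("</table></body></html>")
    return "\n".join(rows)


def parse_raw(text: str) -> pd.DataFrame:
    """Re-parse a raw rendering into a DataFrame (numbers recovered as
    floats) — the inverse used by the round-trip check."""
    lines = [l for l in text.split("\n") if l]
    header = lines[0].split("\t")
    rows = [l.split("\t") for l in lines[1:]]
    frame = pd.DataFrame(rows, columns=header).set_index(header[0])
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        if not converted.isna().all():
            frame[col] = converted
    return frame
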