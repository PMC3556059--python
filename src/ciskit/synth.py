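"""Synthetic planted-motif datasets with companion feature tracks.

Real binding-site benchmarks pair curated answer keys with genome
annotation (conservation, DNase, ChIP peaks ...).  This generator
emulates that setting at desk scale: background DNA is sampled from a
Markov model, binding sites are sampled from a PWM and implanted
without overlap at positions drawn from a configurable law, and each
synthetic feature track mixes the (smoothed) answer coverage with
independent noise at an informativeness level rho in [0, 1] — rho = 1
is a perfectly informative feature, rho = 0 pure noise.  A matched
control track holds the same background with no implants.  Everything
is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (BASES, CiskitError, DNATrack, GenomicSequence, Motif,
                   NumericTrack, Region, RegionTrack, SequenceSet)
from .motifs import BackgroundModel, sample_background, train_background
from .ops import regions_to_numeric, sliding_window

ANSWER_SMOOTHING_BP = 11  # broadens point answers the way epigenetic signals are broad


@dataclass
class PlantSpec:
    """The stated world of one planted-motif dataset."""

    motif: Motif
    n_sequences: int = 10
    length: int = 500
    background: Optional[BackgroundModel] = None  # uniform order-0 if omitted
    sites_per_sequence: object = 2        # int, or ("poisson", lam)
    position_law: Tuple = ("uniform",)    # or ("gaussian", center, sd), TSS-relative
    strand_p: float = 0.5                 # P(site implanted on '+')
    features: Dict[str, float] = field(default_factory=dict)  # name -> rho
    # feature noise law: real epigenomic tracks are bursty, so the default
    # is heavy-tailed (lognormal); ("uniform",) gives flat noise instead
    noise_law: Tuple = ("lognormal", -1.5, 1.0)
    seed: int = 0
    name_prefix: str = "seq"

    def __post_init__(self):
        if self.seed is None:
            raise CiskitError("a seed is mandatory")
        if not (0.0 <= self.strand_p <= 1.0):
            raise CiskitError("strand_p must be in [0, 1]")
        for name, rho in self.features.items():
            if not (0.0 <= rho <= 1.0):
                raise CiskitError(f"feature {name!r}: rho must be in [0, 1]")
        if self.motif.width >= self.length:
            raise CiskitError("motif width must be smaller than sequence length")


@dataclass
class PlantedBundle:
    sequences: SequenceSet
    dna: DNATrack
    answer: RegionTrack
    features: Dict[str, NumericTrack]
    control: DNATrack


def _uniform_background() -> BackgroundModel:
    return BackgroundModel(0, [{"": np.full(4, 0.25)}], trained_on="uniform")


def _sample_site(motif: Motif, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=motif.matrix[:, j])]
                   for j in range(motif.width))


def _reverse_complement(s: str) -> str:
    from .core import reverse_complement
    return reverse_complement(s)


def _draw_position(law: Tuple, length: int, width: int, tss: int,
                   rng: np.random.Generator) -> int:
    if law[0] == "uniform":
        return int(rng.integers(0, length - width + 1))
    if law[0] == "gaussian":
        _, center, sd = law
        pos = int(round(rng.normal(tss + center, sd)))
        return min(max(pos, 0), length - width)
    raise CiskitError(f"unknown position law {law[0]!r}")


def _place_sites(spec: PlantSpec, rng: np.random.Generator, n_sites: int,
                 tss: int, occupied: List[Tuple[int, int]],
                 width: int) -> List[int]:
    placed = []
    for _ in range(n_sites):
        for _attempt in range(1000):
            pos = _draw_position(spec.position_law, spec.length, width, tss, rng)
            if all(pos + width <= s or pos >= e for s, e in occupied):
                occupied.append((pos, pos + width))
                placed.append(pos)
                break
        else:
            raise CiskitError("could not place sites without overlap after 1000 tries")
    return placed


def _site_count(spec: PlantSpec, rng: np.random.Generator) -> int:
    s = spec.sites_per_sequence
    if isinstance(s, tuple) and s[0] == "poisson":
        return int(rng.poisson(s[1]))
    return int(s)


def _sample_noise(law: Tuple, length: int, rng: np.random.Generator) -> np.ndarray:
    if law[0] == "lognormal":
        return rng.lognormal(law[1], law[2], length)
    if law[0] == "uniform":
        return rng.random(length)
    raise CiskitError(f"unknown noise law {law[0]!r}")


def _feature_tracks(spec_features: Dict[str, float], answer: RegionTrack,
                    sequences: SequenceSet, rng: np.random.Generator,
                    noise_law: Tuple = ("lognormal", -1.5, 1.0)
                    ) -> Dict[str, NumericTrack]:
    out: Dict[str, NumericTrack] = {}
    coverage = regions_to_numeric(answer, "coverage")
    smoothed = sliding_window(coverage, "mean", ANSWER_SMOOTHING_BP)
    for fname, rho in spec_features.items():
        raw = {}
        for seq in sequences:
            noise = _sample_noise(noise_law, seq.length, rng)
            raw[seq.name] = rho * smoothed[seq.name] + (1 - rho) * noise
        track = NumericTrack(sequences, raw)
        allv = np.concatenate([track[n] for n in track.names])
        mn, mx = float(allv.min()), float(allv.max())
        span = mx - mn if mx > mn else 1.0
        out[fname] = NumericTrack(sequences,
                                  {n: (track[n] - mn) / span for n in track.names})
    return out


def generate_planted_dataset(spec: PlantSpec) -> PlantedBundle:
    """Sample background DNA, implant motif sites without overlap, and
    derive answer key, feature tracks and a site-free control."""
    rng = np.random.default_rng(spec.seed)
    background = spec.background or _uniform_background()
    sequences = SequenceSet(
        GenomicSequence(f"{spec.name_prefix}_{i + 1}", f"{spec.name_prefix}_{i + 1}",
                        0, spec.length, "+", "synthetic", tss_offset=spec.length)
        for i in range(spec.n_sequences))
    dna_data, control_data = {}, {}
    answer: Dict[str, List[Region]] = {}
    for seq in sequences:
        bg = sample_background(background, spec.length,
                               int(rng.integers(0, 2 ** 31)))
        control_data[seq.name] = bg
        chars = list(bg)
        n_sites = _site_count(spec, rng)
        occupied: List[Tuple[int, int]] = []
        regions = []
        for pos in _place_sites(spec, rng, n_sites, spec.length, occupied,
                                spec.motif.width):
            site = _sample_site(spec.motif, rng)
            strand = "+" if rng.random() < spec.strand_p else "-"
            implant = site if strand == "+" else _reverse_complement(site)
            chars[pos:pos + spec.motif.width] = implant
            regions.append(Region(pos, pos + spec.motif.width, spec.motif.id,
                                  1.0, strand))
        dna_data[seq.name] = "".join(chars)
        answer[seq.name] = regions
    answer_track = RegionTrack(sequences, answer)
    features = _feature_tracks(spec.features, answer_track, sequences, rng,
                               spec.noise_law)
    return PlantedBundle(sequences, DNATrack(sequences, dna_data), answer_track,
                         features, DNATrack(sequences, control_data))


@dataclass
class ModuleBundle(PlantedBundle):
    answer_sites: RegionTrack = None
    answer_modules: RegionTrack = None


def generate_module_dataset(spec: PlantSpec, second_motif: Motif,
                            gap_law: Tuple = ("fixed", 5)) -> ModuleBundle:
    """Implant motif *pairs* (first motif, gap, second motif) with gaps
    drawn from the gap law; the answer includes both the flat site track
    and module-level regions carrying the member sites as children."""
    rng = np.random.default_rng(spec.seed)
    background = spec.background or _uniform_background()
    wA, wB = spec.motif.width, second_motif.width
    max_gap = gap_law[1] if gap_law[0] == "fixed" else gap_law[2]
    if wA + wB + max_gap >= spec.length:
        raise CiskitError("combined module span must be smaller than sequence length")
    sequences = SequenceSet(
        GenomicSequence(f"{spec.name_prefix}_{i + 1}", f"{spec.name_prefix}_{i + 1}",
                        0, spec.length, "+", "synthetic", tss_offset=spec.length)
        for i in range(spec.n_sequences))
    dna_data, control_data = {}, {}
    sites: Dict[str, List[Region]] = {}
    mods: Dict[str, List[Region]] = {}
    module_id = f"{spec.motif.id}_{second_motif.id}_module"
    for seq in sequences:
        bg = sample_background(background, spec.length,
                               int(rng.integers(0, 2 ** 31)))
        control_data[seq.name] = bg
        chars = list(bg)
        n_mods = _site_count(spec, rng)
        occupied: List[Tuple[int, int]] = []
        seq_sites, seq_mods = [], []
        for _ in range(n_mods):
            if gap_law[0] == "fixed":
                gap = int(gap_law[1])
            elif gap_law[0] == "uniform":
                gap = int(rng.integers(gap_law[1], gap_law[2] + 1))
            else:
                raise CiskitError(f"unknown gap law {gap_law[0]!r}")
            span = wA + gap + wB
            for _attempt in range(1000):
                pos = int(rng.integers(0, spec.length - span + 1))
                if all(pos + span <= s or pos >= e for s, e in occupied):
                    occupied.append((pos, pos + span))
                    break
            else:
                raise CiskitError("could not place modules without overlap")
            sA = _sample_site(spec.motif, rng)
            sB = _sample_site(second_motif, rng)
            chars[pos:pos + wA] = sA
            chars[pos + wA + gap:pos + span] = sB
            rA = Region(pos, pos + wA, spec.motif.id, 1.0, "+")
            rB = Region(pos + wA + gap, pos + span, second_motif.id, 1.0, "+")
            seq_sites.extend([rA, rB])
            seq_mods.append(Region(pos, pos + span, module_id, 2.0, ".",
                                   children=[rA.copy(), rB.copy()]))
        dna_data[seq.name] = "".join(chars)
        sites[seq.name] = seq_sites
        mods[seq.name] = seq_mods
    site_track = RegionTrack(sequences, sites)
    mod_track = RegionTrack(sequences, mods)
    features = _feature_tracks(spec.features, site_track, sequences, rng,
                               spec.noise_law)
    return ModuleBundle(sequences, DNATrack(sequences, dna_data), site_track,
                        features, DNATrack(sequences, control_data),
                        answer_sites=site_track, answer_modules=mod_track)


def write_bundle(bundle: PlantedBundle, directory) -> None:
    """Write a bundle as plain-text files loadable by the io module:
    FASTA (dna, control), GFF (answer), one WIG per feature, and an XML
    echo of the member list."""
    import os
    import xml.etree.ElementTree as ET
    from . import io as track_io

    os.makedirs(directory, exist_ok=True)
    track_io.write_track(bundle.dna, os.path.join(directory, "dna.fasta"), "fasta")
    track_io.write_track(bundle.control, os.path.join(directory, "control.fasta"),
                         "fasta")
    track_io.write_track(bundle.answer, os.path.join(directory, "answer.gff"), "gff")
    for fname, track in bundle.features.items():
        track_io.write_track(track, os.path.join(directory, f"{fname}.wig"), "wig")
    root = ET.Element("bundle")
    for seq in bundle.sequences:
        ET.SubElement(root, "sequence", name=seq.name, length=str(seq.length))
    for fname in bundle.features:
        ET.SubElement(root, "feature", name=fname)
    ET.ElementTree(root).write(os.path.join(directory, "bundle.xml"))
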