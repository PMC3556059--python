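import numpy as np
import pytest

from ciskit import (DNATrack, GenomicSequence, Motif, NumericTrack, Region,
                    RegionTrack, SequenceSet, motif_from_sites)


@pytest.fixture
def seqs():
    return SequenceSet([
        GenomicSequence("s1", "chr1", 100, 130, "+", tss_offset=20),
        GenomicSequence("s2", "chr1", 300, 330, "-", tss_offset=10),
    ])


@pytest.fixture
def dna(seqs):
    return DNATrack(seqs, {
        "s1": "ACGTACGTACCCAATGGGGTTTTAAAACCC",
        "s2": "TTTTGGGGCCCCAAAAACGTACGTACGTAC",
    })


@pytest.fixture
def cons(seqs):
    rng = np.random.default_rng(7)
    return NumericTrack(seqs, {n: rng.random(30) for n in seqs.names})


@pytest.fixture
def sharp_motif():
    """Strongly informative 5 bp motif (consensus ACGTA)."""
    return motif_from_sites(["ACGTA"] * 20, "sharp")


@pytest.fixture
def region_track(seqs):
    return RegionTrack(seqs, {
        "s1": [Region(2, 8, "A", 0.5, "+", {"note": "x"}),
               Region(10, 15, "B", 0.9, "-")],
        "s2": [Region(0, 4, "A", 0.2, ".")],
    })


def random_motif(rng, width):
    counts = rng.integers(0, 20, size=(4, width)).astype(float) + 1
    return Motif(f"rnd{rng.integers(1e9)}", counts / counts.sum(axis=0))
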