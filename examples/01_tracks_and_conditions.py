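"""Feature tracks and condition-driven operations.

Builds a two-sequence dataset with a repeat annotation and a
conservation signal, masks repeat bases, and filters predicted sites by
average conservation — the standard pre/post-processing moves of a
binding-site analysis.
"""

import numpy as np

from ciskit import (AvgWithin, DNATrack, GenomicSequence, NumericTrack, Region,
                    RegionTrack, SequenceSet, filter_regions, mask,
                    sequence_statistic, sliding_window)

rng = np.random.default_rng(0)
seqs = SequenceSet([GenomicSequence("promA", "chr1", 1000, 1100),
                    GenomicSequence("promB", "chr2", 5000, 5100)])
dna = DNATrack(seqs, {n: "".join(rng.choice(list("ACGT"), 100))
                      for n in seqs.names})
repeats = RegionTrack(seqs, {"promA": [Region(10, 30, "LINE")],
                             "promB": [Region(50, 70, "SINE")]})
conservation = NumericTrack(seqs, {n: rng.random(100) for n in seqs.names})

masked = mask(dna, "N", repeats)
n_masked = sum(masked[n].count("N") for n in seqs.names)
print(f"masked {n_masked} repeat bases with N")
# 40 = the total repeat coverage: masking touches exactly the annotated bases

gc = sequence_statistic(dna, "gc_content")
for n in seqs.names:
    print(f"{n}: GC = {gc[n]:.3f}")
# the fraction of G/C among called bases, per sequence

smoothed = sliding_window(conservation, "mean", 11)
sites = RegionTrack(seqs, {"promA": [Region(12, 20, "site", 0.9),
                                     Region(60, 68, "site", 0.8)],
                           "promB": [Region(40, 48, "site", 0.7)]})
kept = filter_regions(sites, AvgWithin(smoothed, ">=", 0.5))
print(f"conservation filter kept {kept.count()} of {sites.count()} sites")
# sites whose mean smoothed conservation is below 0.5 are discarded
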