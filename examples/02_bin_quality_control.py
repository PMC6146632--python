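"""Estimate bin completeness from marker genes and filter for retention.

A bin is kept when at least 10% of the 137-gene single-copy marker panel
is present AND at least 2 of the 4 metagenomic samples support it (a
sample supports a bin when it maps reads to at least half its contigs).
Contigs under 1000 bp are discarded as singletons beforehand.
"""

from biometha.binqc import BinFilterConfig, completeness, contig_prefilter, filter_bins, sample_support
from biometha.simulate import SimulationConfig, simulate_community

com = simulate_community(SimulationConfig(seed=21, n_bins=12, completeness_range=(0.02, 0.6),
                                          write_sequences=False))

kept, summary = contig_prefilter({**com.contig_lengths, "short_ctg": 680})
print(f"prefilter: removed {summary.n_removed} contig(s), {summary.bp_removed} bp")

for gb in com.bins:
    gb.completeness_pct = completeness(gb.markers_found, com.marker_set)
    sample_support(com.contig_mapping, gb)

retained, decisions = filter_bins(com.bins, BinFilterConfig())
print(f"retained {len(retained)} of {len(com.bins)} bins")
for d in decisions:
    if not d.retained:
        print(f"  rejected {d.bin_id} ({d.completeness_pct:.1f}% complete): {d.failed[0]}")
# Rejections list the failed criterion, mirroring the completeness>=10% /
# support>=2-of-4 retention rule.
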