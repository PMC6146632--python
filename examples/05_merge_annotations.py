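"""Complement a bacterial CDS annotation with archaeal calls at shared loci.

Mixed-background bins get annotated twice (bacterial and archaeal gene
callers); the merge keeps every bacterial CDS, but where an unannotated
bacterial CDS and an annotated archaeal CDS occupy the same locus
(reciprocal overlap > 50%, same strand) the archaeal record wins, and
archaeal CDS at fresh loci are appended.
"""

from biometha.io import merge_annotations
from biometha.reference import ECNumber, GeneRecord


def cds(gid, start, end, ec=None):
    return GeneRecord(gene_id=gid, contig_id="ctg1", start=start, end=end, strand="+",
                      ec_codes=[ECNumber.parse(ec)] if ec else [])


bacterial = [
    cds("bact_1", 100, 700, ec="3.2.1.4"),   # annotated: always kept
    cds("bact_2", 1000, 1600),               # unannotated, overlapped below
    cds("bact_3", 2000, 2500),               # unannotated, no archaeal rival
]
archaeal = [
    cds("arch_1", 1010, 1590, ec="2.8.4.1"),  # replaces bact_2
    cds("arch_2", 3000, 3800, ec="1.2.99.5"),  # new locus: appended
    cds("arch_3", 120, 680, ec="6.2.1.1"),     # loses to annotated bact_1
]

merged = merge_annotations(bacterial, archaeal)
for g in merged:
    ec = g.ec_codes[0].code if g.ec_codes else "-"
    print(f"{g.gene_id:8s} {g.start:>5}..{g.end:<5} EC {ec}")
print(f"annotated CDS: {sum(g.annotated for g in merged)} of {len(merged)}")
# bact_2 is gone (replaced by arch_1); arch_3 was dropped because an
# annotated bacterial CDS already covers that locus.
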