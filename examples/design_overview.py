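"""Inspect the modified Latin square pool design.

Prints the mixing square, the six pairwise pool comparisons with their
nominal fold changes, and the exclusion bookkeeping.  The fold changes are
the ground truth every downstream ratio measurement is judged against.
"""

from spikeqc import apply_exclusions, enumerate_pool_pairs, load_design
from spikeqc.design import SUBPOOLS

design = load_design()
print(f"{len(design.records)} controls in the design")

print("\nMixing square (percent of each subpool per pool):")
print("subpool  " + "  ".join(f"pool {p}" for p in design.square.pools))
for sub in SUBPOOLS:
    row = "  ".join(f"{design.square.proportion(sub, p):7d}" for p in design.square.pools)
    print(f"   {sub}     {row}")

print("\nPairwise pool comparisons and their titrated fold changes")
print("(subpool A always contributes the 1-to-1 component):")
for pool_i, pool_j, folds in enumerate_pool_pairs(design):
    print(f"  pool {pool_i} vs {pool_j}: {sorted(folds)}")

analysis = apply_exclusions(design)
print(
    f"\nAnalysis set: {len(analysis.records)} controls "
    f"({len(analysis.excluded)} excluded: 7 antisense + 1 omitted background control)"
)
relabelled = [
    (rec.control_id, design.record(rec.control_id).subpool, rec.subpool)
    for rec in analysis.records
    if design.record(rec.control_id).subpool != rec.subpool
]
for cid, old, new in relabelled:
    print(f"  {cid} analysed under subpool {new} (labelled {old}; known mixing error)")
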