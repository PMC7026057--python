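"""Rank candidate reference genes with all four stability algorithms.

Simulates a 12-candidate RT-qPCR screen across four meiotic stage groups
(PM, PRO, TT, IP; 3 biological x 2 technical replicates), scores every
candidate with geNorm, NormFinder, BestKeeper and the comparative
delta-Ct method, and aggregates the four rankings into the consensus
order (geometric mean of ranks).
"""

from cqnorm import SimConfig, rank_genes, simulate_cq_dataset, stability_scores_table

ds, truth = simulate_cq_dataset(SimConfig(seed=42))
report = rank_genes(ds)

print(stability_scores_table(report).round(3))
print()
print("consensus order (most stable first):", ", ".join(report.consensus.order))
print("truly unstable genes (by construction):", ", ".join(truth.true_stability_order[-3:]))

# Lower scores mean more stable expression. geNorm M and the delta-Ct
# score are SDs of pairwise log2 ratios (log2 units / cycles); NormFinder
# rho combines intra-group variance with shrunken inter-group shifts;
# BestKeeper reports the mean absolute deviation of raw Cq in cycles.
# The three genes the generator destabilized should sit at the bottom.
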