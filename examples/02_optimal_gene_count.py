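"""How many reference genes are enough? The pairwise-variation series.

Builds normalization factors NF_n from the top-n consensus genes and
computes V_n/n+1, the SD of log2(NF_n/NF_n+1) over samples.  The first n
with V below the 0.15 cutoff is the recommended gene count: adding the
(n+1)-th gene no longer changes the normalization factor appreciably.
"""

from cqnorm import SimConfig, rank_genes, simulate_cq_dataset

ds, _ = simulate_cq_dataset(SimConfig(seed=42))
report = rank_genes(ds, cutoff=0.15)

series = report.v_series
for n, v in series.v.items():
    flag = "  <- first below 0.15" if n == series.optimal_n else ""
    print(f"V_{n}/{n + 1} = {v:.4f}{flag}")
print()
print(f"recommended number of reference genes: {series.optimal_n}")
print("recommended set:", ", ".join(report.recommended))

# With 9 genuinely stable candidates the series drops under the cutoff
# immediately: two well-chosen genes already give a stable NF.  Real
# designs with heterogeneous tissues typically need three or more.
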