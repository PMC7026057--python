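# Methods

## Data model and preprocessing

A Cq experiment is a long table of quantitation cycles (gene × sample ×
technical replicate) with per-sample metadata (group/stage, genotype,
tissue, biological replicate) and per-amplicon mean PCR efficiencies
E ∈ (1, 2.2] (2 = perfect doubling). Technical replicates are collapsed
by the arithmetic mean of Cq — the qBase convention, monotone-equivalent
to the geometric mean of quantities; the collapse rule is recorded in
the table's provenance. Replicate disagreement beyond 0.5 cycles, Cq
outside (0, 45] and E > 2 are QC warnings, never errors; the tokens
`NA`, `NaN`, empty, `Undetermined` mark missing reactions. Stability
analysis requires a complete gene × sample matrix; the completeness
filter either raises naming the offending cells (`strict`) or drops
genes with any missing cell (`drop-gene`, the situation of a candidate
not expressed in some genotype).

Efficiency correction rescales cycles to perfect-doubling units,
CqE = Cq·log(E)/log(2) = Cq·log₂E (the base of the log ratio is
irrelevant), so that all later algebra is exact in log₂. Relative
quantities are q = 2^(CqE₀ − CqE) with CqE₀ a per-gene calibrator,
by default the gene's minimum CqE (most expressed sample, so
q ∈ (0, 1]). Every stability score and fold change downstream is
invariant to the calibrator choice; this is tested explicitly.

## Stability algorithms

**geNorm.** V_jk = SD over samples of log₂(q_j/q_k); M_j = mean over
k≠j of V_jk. Ranking is by iterative elimination: recompute M on the
surviving set, remove the gene with the largest M, repeat until two
genes remain. The final pair is jointly most stable; its ranks 1 and 2
are assigned by full-set M with a lexicographic tie-break so the output
is deterministic (a requirement for the consensus step). All SDs in the
package use the n−1 sample denominator.

**Pairwise variation.** NF_n(s) = geometric mean of the top-n ranked
genes' quantities; V_n/n+1 = SD over samples of log₂(NF_n/NF_n+1),
n = 2 … n_max−1. Implemented as a cumulative mean in log₂ space.

**NormFinder.** Input is any log₂-scale expression matrix (−CqE or
log₂ q; the estimator is invariant to per-gene additive offsets). Per
group g, values are centered per sample over the k genes
(z = y − ȳ_genes), giving d̄_ig (group mean) and s²_ig (sample
variance, n_g−1). The centering makes naive variances biased, so the
corrected intra-group variance is
σ̂²_ig = max(0, (k/(k−2))·(s²_ig − S_g/(k(k−1)))), S_g = Σ_i s²_ig —
unbiased for the gene's own variance and truncated at zero (the
method-of-moments estimator can go negative). With one group the
stability value is ρ_i = σ̂_i. With G ≥ 2 groups, d_ig = d̄_ig − mean
over groups, the inter-group variance is
γ̂² = max(0, Σ d²/((k−1)(G−1)) − mean(σ̂²_ig/n_g)) ((k−1)(G−1) free
dimensions after the two centerings), differences are shrunk
d̃_ig = d_ig·γ̂²/(γ̂² + σ̂²_ig/n_g), and
ρ_i = mean over g of (|d̃_ig| + posterior SD). Requires k ≥ 3 and
n_g ≥ 2. The estimator is validated by parameter recovery (single-group
σ² recovered within a few permille of truth at k = 10, n = 50) and by
ranking behavior (noisy and group-shifted genes rank last), not by
matching another tool's scores digit for digit.

**BestKeeper.** Operates on raw Cq (switchable to CqE). Per gene:
arithmetic and geometric mean, min, max, the dispersion `sd_cq` = mean
absolute deviation from the arithmetic mean (cycles; the tool's
"SD [±Cq]" is an average-deviation statistic — the deviation base is
not standardized, arithmetic mean chosen here), CV% = 100·sd_cq/mean,
and Pearson r (with two-sided p) against the BestKeeper index, the
per-sample geometric mean of all candidates' Cq. Genes with
sd_cq > 1 cycle are flagged inconsistent; zero-variance genes get an
undefined r with a warning, not an error. Ranking for the consensus
uses sd_cq ascending (r is reported, not ranked on).

**Comparative ΔCt.** pair_sd[j,k] = SD over samples of Cq_j − Cq_k;
score_j = mean over k≠j. On CqE by default (switchable to raw Cq).
Note the identity ΔCq_jk = log₂(q_k/q_j) + const, so the ΔCt score on
CqE equals the full-set geNorm M from the derived quantities exactly —
the two methods differ only in geNorm's iterative elimination. This
identity serves as a cross-implementation oracle in the tests.

## Consensus and the number of reference genes

Each method's scores become ranks (ties → average rank; geNorm
contributes its iterative-elimination rank, not the full-set-M rank);
the consensus score is the geometric mean of the four ranks, ordered
ascending with arithmetic-mean-then-lexicographic tie-breaks. How the
aggregated tools handle ties internally is undocumented; average ranks
keep the aggregate well-defined and deterministic.

The recommended gene count is read off the V series computed along the
consensus order: the first n with V_n/n+1 below the cutoff
(default 0.15, configurable — the cutoff is a guideline, not a law).
If no V falls below the cutoff the count is reported undefined with a
recommendation to keep the full panel.

## Quantification and statistics

NF(s) = geometric mean of the selected RGs' quantities;
rel(s) = q_GOI(s)/NF(s); fold(s) = rel(s)/mean(rel over calibrator
samples), so the calibrator group's folds average exactly 1.
Per-group means and standard errors accompany the folds. The defining
property — a shared per-sample loading factor multiplying every gene
cancels exactly — is tested both algebraically and through the
generator's noise-free limit. Fold changes are computed per biological
replicate (not from group-mean quantities): the replicate-level values
are what the statistics need.

Statistics run on log₂ folds (ratios are log-normal under the
generative model; Shapiro–Wilk per group is reported so users can judge
the normality assumption): one-way ANOVA, Tukey HSD all pairs, and
two-tailed Dunnett vs the control group (α = 0.05; asterisks
\* p < 0.05, \*\* p < 0.01), all via scipy. The compact letter display
is built from the maximal cliques of the graph whose edges are
non-significant Tukey pairs — every edge lies in a maximal clique and
non-adjacent groups share none, so "two groups share a letter iff not
significantly different" holds exactly, not heuristically.

**Reduction study.** For n from the recommended count down to 2, NF_n
is built from the top-n consensus genes and the GOI's folds are
recomputed. Within each sample group, log₂ folds are compared across
the NF variants by ANOVA + Tukey (unpaired one-way layout; the variants
share replicates, making the test conservative in the correlated
direction); each variant's Dunnett pattern is compared with the
recommended one. A level is safe if no group shifts (all Tukey p ≥ α
vs the reference level) and the star pattern is identical;
`minimal_safe_n` is the smallest n reachable from n_rec through safe
levels only. When within-variant spread is at floating-point level
(noise-free data) the level means are compared directly at 1e-9
tolerance instead of feeding rounding error to Tukey.

## Synthetic data generator

Latent CqE[g,s] = μ_g + λ_s + shift[g, group(s)] + b[g,s], with
μ_g ~ U(20, 30) (the observed Cq range), λ_s ~ N(0, τ²) a per-sample
loading factor shared by all genes (RNA input / RT yield; τ = 0.5
cycles), b ~ N(0, σ_g²) biological noise, and raw
Cq = CqE·log(2)/log(E_g) — the exact inverse of the efficiency
correction, so correction round-trips to machine precision.
E_g ~ U(1.900, 1.946), the efficiency range of the emulated assay
panel. Technical replicates add N(0, σ_tech²), σ_tech = 0.1 cycles.
Defaults: 12 candidates — 9 stable (σ = 0.15), 2 high-noise (σ = 1.0)
and 1 shifted by 1.5 cycles in one group (TT; the choice of group is
arbitrary and fixed) — across PM/PRO/TT/IP with 3 biological × 2
technical replicates. The two unstable flavors are deliberate:
high-noise genes are caught by every method, whereas a coordinated
group shift is the co-regulation failure mode pairwise methods are
partially blind to and the model-based method is not.

A gene of interest can be drawn sharing the same λ_s (so normalization
has something real to remove) with a per-group log₂ fold profile
(default staged repression 0, 0, −1, −2) and its own noise
(σ = 0.15) and efficiency; it uses an independent seeded stream so
adding it never perturbs the candidate draw. All draws follow a
documented order from a single seed; identical seeds give bit-identical
datasets.

What the generator does **not** emulate: amplification-curve shape and
efficiency estimation error (efficiencies are inputs), inter-run
effects and plate calibrators, correlated co-regulated gene modules
beyond the single-shift flavor, non-Gaussian outliers, and
missingness mechanisms (dropouts must be injected explicitly). Passing
tests therefore demonstrate correctness of the estimators and pipeline
under a well-specified generative model, not robustness to every
artifact of real qPCR data.

## Problem sizes and numerical choices

Monte-Carlo checks in the tests and the acceptance script use 20–100
seeded replicates per property and the default 12 × 12 design (or the
stated smaller designs for single-property checks) — small enough to
run anywhere, large enough that the 95%-of-seeds acceptance thresholds
have comfortable margins. Degenerate inputs are handled explicitly:
zero-variance genes (BestKeeper r undefined → warning), all-identical
groups (Shapiro/ANOVA → NaN, no letters conflict), negative variance
estimates (truncated at 0), noise-free reduction comparisons (direct
mean comparison). Ties anywhere resolve deterministically
(lexicographic after the relevant score).

## Known limitations

- BestKeeper's descriptive statistics follow the published definitions,
  but the original tool's exact deviation base is unspecified; rankings
  (its role here) are insensitive to the choice.
- The NormFinder γ̂² denominator follows the published model's
  degrees-of-freedom accounting; other implementations differ in
  small-G corrections. Rankings are validated by simulation.
- The reduction study's unpaired across-variant layout ignores the
  replicate pairing across NF variants; a mixed model would gain power.
- No inter-run calibration or efficiency-uncertainty propagation.
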