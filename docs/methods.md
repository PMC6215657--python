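# Methods

## The statistic

For a gene measured in `n` tumor and `m` normal samples, define the
up-regulation event U (higher expression in tumor than in normal) and the
down-regulation event D. The target quantity is `T = P(U) − P(D) ∈ [−1, 1]`.

Each tumor value `a₁ᵢ` receives an exceedance proportion
`lᵢ = (1/m) Σⱼ I(a₁ᵢ ≥ a₂ⱼ)`, and each normal value `a₂ⱼ` receives
`kⱼ = (1/n) Σᵢ I(a₂ⱼ ≤ a₁ᵢ)`. Both measure, per sample, how far tumor
expression sits above normal; `lᵢ` is a multiple of `1/m`, `kⱼ` of `1/n`.

**GRP.** Fix a confidence cutoff `τ ∈ [0.5, 1]` and discretize each
proportion `p` into a regulation status: `+1` if `p ≥ τ`, `−1` if
`1 − p > τ` (equivalently `p < 1 − τ`, strict), `0` otherwise. The `≥`/`>`
asymmetry is deliberate: at `τ = 0.5` every sample is classified (no
zeros). With empirical class priors `n/(n+m)`, `m/(n+m)`, the
total-probability estimate reduces to vote counting over all samples:
`P(U) = s_u/(n+m)` with `s_u` the number of `+1` statuses, and
`P(D) = s_d/(n+m)` with `s_d` the number of `−1` statuses. A `+1` status
is up-evidence on *either* block: `lᵢ ≥ τ` means tumor sample i sits above
most normal samples, and `kⱼ ≥ τ` means normal sample j sits below most
tumor samples. (An alternative bookkeeping that flips the sign of the
normal block's votes appears in parts of the literature; it makes a
completely separated gene score T = 0 and destroys the cutoff-free limit
below, so this package uses the total-probability counting throughout.)
At `τ = 0.5`, `s_u + s_d = n + m` exactly (S = P(U) + P(D) = 1); for
`τ > 0.5`, S ≤ 1 and decreases with τ.

**aGRP.** Remove the cutoff and average the proportions:
`P(U) = (Σlᵢ + Σkⱼ)/(n+m)`, `P(D) = 1 − P(U)`, `T = 2·P(U) − 1`. Since
`Σlᵢ·m = Σkⱼ·n = U` (the count of pairs with `a₁ᵢ ≥ a₂ⱼ`), this is
`T = 2U/(nm) − 1`: an unbiased estimate of `P(Y₁ ≥ Y₂) − P(Y₁ < Y₂)` and a
rescaled Mann–Whitney exceedance probability. GRP at `τ = 0.5` is its
sign-vote coarsening; as τ → 0 (conceptually) GRP tends to aGRP.

**Ties.** The indicators are `≥` and `≤` exactly, so a tie counts as
exceedance in both directions and a gene constant across all samples
scores T = 1. This pathology is documented rather than patched: the
coefficient-of-variation filter (below) removes such genes before
analysis, and all statistics are otherwise unchanged by any strictly
increasing transform of a gene's values.

## Significance

**Asymptotic engine.** For normal class distributions
`Y₁ ~ N(μ₁, σ₁²)`, `Y₂ ~ N(μ₂, σ₂²)`, the per-pair exceedance probability
is `q = Φ((μ₁−μ₂)/√(σ₁²+σ₂²))` and the statistic is approximately
`N(2q − 1, 2(n²+m²)q(1−q)/(nm(n+m)²))`; under the null (q = 1/2) this is
`N(0, (n²+m²)/(2nm(n+m)²))`. Two-sided p-values are `2(1 − Φ(|T|/σ₀))`,
clipped to machine epsilon from below. Note that this variance rests on an
independence approximation across the per-sample proportions and is
several-fold smaller than the exact relabelling variance of T, which for
tie-free data is `(n+m+1)/(3nm)` (from `Var(U) = nm(n+m+1)/12`): 0.0025
vs 0.07 at n = m = 10. The asymptotic engine is therefore
anti-conservative and is provided as stated, not as the default.

**Permutation engine (default).** B random shuffles of the sample-label
vector are drawn once and shared by all genes (cheaper, and p-values are
comparable across genes); per gene,
`p = (1 + #{b : |T_b| ≥ |T_obs|})/(B + 1)`, so `p ≥ 1/(B+1)` and never 0.
Default B = 1000. An exhaustive engine enumerating all C(n+m, n)
labelings is available for small designs and is the oracle the
Monte-Carlo engine is tested against.

*Implementation.* For a gene with all-distinct values, the pair count
under any relabelling is `Σ_{i∈tumor} Lᵢ − n(n+1)/2` with `Lᵢ` the
precomputed rank of value i among all n + m values, so B relabellings per
gene cost one (genes × samples) × (samples × B) matrix product. GRP
additionally needs per-sample threshold counts; these come from a single
cumulative sum over the presorted order per relabelling. Genes containing
tied values fall back to exact pairwise counting per relabelling. Both
paths implement the same indicators exactly; the split is purely for
speed. Comparisons of integer counts against `τ·m` use a 1e-9 guard so
that binary representation of τ never flips a boundary case.

**Multiple testing.** Benjamini–Hochberg step-up adjustment
(statsmodels). Tests are two-sided throughout; direction is reported
separately as the sign of T for genes significant at the configured
level.

## Simulators

**Two-normal design** (`simulate_simple`). Group I: `G = 1000` null genes
i.i.d. N(0, 1) in all 2n samples. Group II: `G = 1000` differentially
expressed genes, N(δ, σ²) in tumor and N(0, σ²) in normal with δ = 0.15,
σ = 0.1 by default, giving `q = Φ(0.15/(0.1√2)) ≈ 0.8556` and mean
statistic `2q − 1 ≈ 0.711`. The shifted mean is assigned to the tumor
class so that true DE genes have positive T. Used for the type-I error /
power study at n ∈ {6, 10, 20, 50} per class.

**Clumped-correlation design** (`simulate_clumped`). Emulates a
heterogeneous microarray experiment: G = 10,000 genes split 6,000 null /
2,000 up / 2,000 down by default. Genes are partitioned into clumps by
drawing sizes i.i.d. uniform on {1..100} until G is covered (last clump
truncated); each clump gets a compound-symmetry noise correlation
ρ ~ U(0.5, 1), realized as `√(1−ρ)·own + √ρ·shared` normal draws (always
positive semi-definite, no factorization needed). Per-gene baseline means
are `μ_g ~ 1000·χ²₅` (expectation 5000, intensity-scale units) with noise
scale `ω_g = e^{β₀/2} μ_g^{β₁/2}`; defaults β₀ = −5, β₁ = 2 make the
coefficient of variation constant at `e^{−2.5} ≈ 8.2%`. DE genes multiply
(up) or divide (down) the tumor-class mean by
`r_g = 1 + 2^{−1/2} e^{β₀/2} δ_g`, δ_g ~ U(1, 2) — ratios in
(1.058, 1.116), a deliberately subtle effect in the regime where partial
power at small n is the interesting outcome. The noise scale of the
shifted class is recomputed from its own mean (constant CV); a
`shared_omega` flag keeps the baseline scale instead. The δ range is a
parameter for stronger designs. DE labels are placed uniformly at random,
independent of clump membership; clump structure is redrawn per
replicate. Values are real-valued (normal noise on a positive mean);
occasional negative values are left untouched since every statistic is
rank-based.

*What the simulators do not emulate:* count-distribution noise
(negative binomial overdispersion), batch effects, paired designs,
missingness, probe-level artifacts. Passing the benchmarks therefore
shows correct behaviour under heterogeneous correlated Gaussian noise
with subtle multiplicative effects, not under every failure mode of real
data.

Marginal per-gene power depends only on (μ_g, ω_g, r_g, n): the clump
correlation shapes across-gene dependence (and hence replicate-to-replicate
variance of the metrics), not each gene's marginal distribution.

## Evaluation

A gene is called positive iff raw p < α (default α = 0.05; BH-adjusted
values are used in the real-data workflow, raw p in the simulation
benchmarks). Sensitivity is the called fraction of truly DE genes,
specificity the uncalled fraction of null genes, accuracy the overall
agreement; a metric whose truth class is empty is reported as absent, not
as 0. ROC AUC ranks genes by |T| with ties broken by smaller p (a
configurable choice; `1 − p` ranking is also available) and is verified
against brute-force pair enumeration. Replicate studies report
mean ± std in percent.

The consistency analysis bins genes by |T| into intervals
`(η, η + 0.1]` for η ∈ {0.5,…,0.9} (the lowest interval also includes its
left endpoint, so a boundary value belongs to the lower interval only)
and reports, per interval, the fraction of the union of member genes
present in all datasets and the fraction of those common genes with a
single sign everywhere. Empty unions report NaN.

## Preprocessing

Probe-level matrices are collapsed by arithmetic mean over probes mapping
to the same gene id (unmapped probes dropped and logged). The CV filter
retains genes with `std/|mean| ≥ cutoff` (default 0.05, sample std,
computed over all samples jointly, after probe collapsing); genes with
mean 0 are dropped. Low-CV removal both discards uninformative
near-constant genes and removes the all-ties T = 1 pathology. Missing
values are rejected at load time; impute or drop before analysis.

## Problem sizes in the test and benchmark suite

The bundled benchmark checks run the full published-scale designs — 20
replicates of 10,000 genes for the clumped study at n ∈ {10, 20} and 20
replicates of 1000 null genes for the calibration study, B = 1000
permutations throughout (a few seconds per replicate with the vectorized
engine). The n = 50 hard-cutoff scenario uses 5 replicates, which already
pins its replicate-mean accuracy to ±0.15. Tolerances on published
reference values are ±3 printed standard deviations.

## Known limitations

* Two-class, unpaired designs only; no covariates, no multi-group or
  paired variants.
* The asymptotic null is anti-conservative (see above); use permutation
  p-values unless n·m is large enough that recalibration is acceptable
  for screening purposes.
* Permutation p-values are bounded below by 1/(B+1): with B = 1000 and
  thousands of genes, top genes share the floor p and are ordered by |T|.
* The tie convention favours up-regulation on tied pairs; data with heavy
  ties (e.g. zero-inflated counts) should be filtered or jittered
  upstream, or interpreted with the documented convention in mind.
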