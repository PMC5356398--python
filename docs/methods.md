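# Methods

This note documents the models behind `coldnet`, the defaults and why they
were chosen, what the synthetic data generator does and does not emulate, and
the numerical conventions that matter when interpreting results.

## The bilinear expression model and its fit

The network stage assumes log2 expression near a quasi-steady state, so that
A = ΛF + E: each gene's profile is a signed linear mixture of latent TF
activity (TFA) profiles. TFA is not TF mRNA — a TF's regulatory activity can
be post-translationally controlled — which is why F is estimated rather than
read off the expression matrix. The model ignores time lags and saturation;
it is a first-order description of co-regulation, not kinetics.

**Initialization.** The candidate support Λ⁰ overlays two sources: the signed
literature prior Λ_L (entries in {−1, 0, +1}), and expression-derived
candidates Λ_T = sign(ρ) for TF–gene pairs with |Pearson ρ| ≥
`expr_init_threshold` (default 0.8) between the TF's own mRNA row and the
gene row across all M columns. Correlation with the TF's mRNA is the
simplest observable proxy for shared regulation; 0.8 keeps Λ_T conservative
relative to the curated prior. On conflicts the literature sign wins, since
prior edges are experimentally supported. TFs without an expression row
contribute literature edges only; zero-variance TF rows are excluded with a
warning. F is initialized by the ridge solve given Λ⁰.

**Alternating least squares.** Gene rows of Λ (restricted to their candidate
TF sets) and F are updated by exact ridge solves (`ridge` default 10⁻⁶,
numerical stabilization only) until the summed squared change of F falls
below `epsilon` (10⁻⁶) or `max_iter` (500) is reached; non-convergence is
flagged on the result, not raised, because the slow tail of ALS convergence
is a scale drift that barely moves the fitted network. Each half-step
minimizes the penalized objective ‖A − ΛF‖² + ridge(‖Λ‖² + ‖F‖²) exactly in
its own block, so the recorded objective trace is non-increasing at every
half-step — a property the tests assert. Two indeterminacies of the
bilinear form are resolved by convention *at convergence*: rows of F are
rescaled to unit RMS with the inverse factor absorbed into Λ (pure
reparameterization; ΛF, the residual and the objective are unchanged), and
each (Λ column, F row) pair is sign-flipped when the majority of its fitted
signs disagree with the signed candidate support, anchoring signs to the
prior. Rescaling only once, at the end, keeps the recorded objective
monotone — rescaling inside the loop would perturb the penalty term without
changing the model.

**Refinement and edge significance.** Per gene, coefficients are
re-estimated by a naive elastic net, minimize ½‖y − Xb‖² + λ₁‖b‖₁ +
(λ₂/2)‖b‖², with λ₁ = `enet_lambda`·`enet_alpha` and λ₂ =
`enet_lambda`·(1 − `enet_alpha`) (defaults 0.01 and 0.5: light shrinkage —
the support is already restricted, and significance filtering does the heavy
lifting). The orthonormal closed form S(b_ols, λ₁)/(1 + λ₂) is asserted in
tests. Genes with a single candidate TF keep their ALS coefficient
(penalized re-estimation of one coefficient only biases it).

Edge p-values use a conditional permutation test: for edge (g, j) the
observed statistic is the fitted |w_gj|, and the null is the
partial-regression coefficient of a column-permuted copy of TF j's activity
profile with the gene's other candidate TFs and an intercept projected out
(B = `n_permutations` = 1999 draws; p = (1 + #{|null| ≥ |w|})/(B + 1), floor
1/(B+1) = 5·10⁻⁴). Permuting only the tested profile keeps the rest of the
gene's regulatory signal in the model, which preserves power for weak edges
on genes that also carry strong ones; B = 1999 makes the floor strictly
smaller than the default retention threshold p₀ = 10⁻³, which is applied as
a strict inequality (p < p₀ retained). A t-approximation
(`pvalue_method="t-approx"`) is available and agrees with the permutation p
to ±0.02 on Gaussian data. The permutation mechanism and these
hyperparameters are this package's explicit choices; all are exposed on
`NetworkALS`.

The fit can be run on the combined M = l·m matrix (one network across
genotypes) or on any per-genotype column subset (per-genotype target counts);
both are just column selections of the input.

## Order-preserving triclustering

Discretization is consecutive-interval coding: symbol U/D/N per interval
depending on whether the log2 difference exceeds ±`delta` (default 0.5, i.e.
~1.4-fold per interval — half the 2-fold gene-level filter). Baseline-relative
coding was the alternative; consecutive coding was chosen because it makes
"similar behavior" local in time and keeps the exhaustive oracle tractable.

Conserved triclusters are maximal in all three dimensions (genes, genotype
subset, time window): a cluster is emitted only when no gene, genotype or
window extension preserves pattern identity. Maximality avoids the
exponential redundancy of reporting every sub-cluster, and the definition is
verified against brute-force enumeration over all (subset, window, pattern)
triples on small instances. By default only the full time course is mined
(`min_window=None`); window mining is available but quadratic in m.

Divergent calls report the minority side of a pattern partition: a gene is
divergent on subset S′ when its pattern (identical within S′) differs from
every complementary genotype. Three divergence types are covered: unique
patterns, sign-flips, and delayed responses — the latter detected as pattern
strings that equal the complement's pattern shifted by up to `max_shift`
(default 1) steps, annotated with the signed shift.

Cluster significance is a binomial tail: p = P(X ≥ |genes|) with X ~
Binomial(n_genes, q), q the null probability of one gene showing the
cluster's pattern in every genotype of its subset — (1/3)^(L·|S′|) under the
uniform symbol null (default), or a product of observed symbol frequencies
under the empirical null. The uniform null is deliberately simple; it
overstates significance for common flat patterns, which is why flat (all-N)
clusters should be pre-empted by the fold-change filter.

## Dynamic regulatory maps

The full input–output HMM of dynamic-regulatory-map miners gates transitions
on TF inputs. Here the map is a Gaussian tree-HMM fit in two phases — greedy
structure growth (a node splits into ≤ `max_children` branches at a time
point when a 1-D Gaussian mixture on that time's values lowers BIC by at
least `min_bic_improvement` = 10, with both branches ≥ `min_branch` = 10
genes) and EM refinement (soft gene-to-path assignment, per-node means/SDs,
log-likelihood non-decreasing, variances floored at 10⁻⁴ with a warning) —
followed by post-hoc hypergeometric TF–branch association. This
simplification preserves the outputs that matter downstream (paths, split
times, TF annotations) while keeping the fit deterministic and testable; the
BIC margin guards against noise-driven bifurcations at desk scale. The root
is anchored at mean 0 because profiles are fold changes against the first
time point, and that column carries no information (it is excluded from the
likelihood). The TF split score is the hypergeometric upper tail of the TF's
target count in a branch given the genes at the split; annotations with
score < 0.005 (the conventional split cutoff) are retained.

## Synthetic data: what it emulates, what it does not

`GenConfig` defaults mirror a 4-cultivar × 8-time-point × 3-replicate
cold-acclimation design with 2.5%-dense signed connectivity, 60% prior
coverage with 10% spurious prior edges, and log2-scale i.i.d. Gaussian noise
of SD 0.25 (a standard post-normalization assumption). TF activities come
from a parametric library (step, transient pulse, ramp) with genotype-level
jitter — mimicking the transient accumulation of cold-response regulators —
with pulses weighted more heavily and base profiles rejection-sampled to
pairwise |correlation| ≤ 0.7, because planted programs that are mutually
near-collinear are unidentifiable for *any* inference method. TF mRNA rows
(noisy copies of the activity profiles) are appended to the matrix so the
expression-based initialization has something to correlate against; in real
data TF mRNA is a weaker proxy for activity than it is here.

Planted conserved/divergent sets are realized as cumulative U/D pattern
offsets of 2.0 log2 units per changing interval (a 4-fold swing per
interval, typical of strongly cold-responsive transcripts); divergence is a
genotype-specific sign-flip or a one-step delay of a shared profile.
Planted pattern strings are drawn avoiding collision with any background
gene's pattern, so that at zero noise every planted set is recovered exactly
— the closed-loop property the acceptance tests exercise. Planted genes
carry no TF edges, so pattern recovery and edge recovery are scored
independently. Bifurcation genes get a step offset (±effect from the split
time) shared across genotypes.

Passing these tests therefore shows that each algorithm recovers the
structure it models under its own assumptions at realistic noise; it does
not show robustness to probe-level artifacts, unbalanced designs,
non-Gaussian noise, TF mRNA/activity decoupling, or regulatory feedback,
none of which the generator simulates.

## Numerical conventions and degenerate inputs

- Expression input to the network stage is row-centered by default
  (`center=True`): the bilinear model has no intercept, and centering
  removes per-gene baselines exactly (A_c = ΛF_c).
- The fold-change filter is inclusive at its threshold ("at least 2-fold" ⇒
  range ≥ 1.0 in log2) and defaults to *any*-genotype scope; per-genotype
  scope is exposed for per-cultivar counts.
- Genes with no candidate TF are carried with empty Λ rows rather than
  dropped, keeping row indices aligned with the filter output.
- The gene-wise ANOVA (y = μ + g + t + g×t + ε) requires a balanced complete
  design and uses the standard SS decomposition, vectorized across genes;
  statsmodels' `anova_lm` is the cross-check in tests.
- Ties in marker ranking break by gene id; all stochastic steps
  (permutations, mixture proposals, generator draws) consume explicit seeds,
  and the pipeline derives every stage seed from the single config seed, so
  reruns are byte-identical.

## Problem sizes

The test-suite and the acceptance script run at desk scale, chosen to make
every property measurable in seconds while preserving the structure of the
full design: n = 100–300 genes, k = 8–10 TFs, M = 32 combined conditions for
network recovery (10 seeds); 200 random instances with n ≤ 15, l ≤ 3, m ≤ 5
for oracle equivalence of the pattern miner; n = 200 genes, 20 seeds for
bifurcation recovery; the default 300-gene configuration for end-to-end
determinism.

## Known limitations

- ALS convergence in ε on F is slow in the scale-drift direction; runs that
  stop at `max_iter` are flagged `converged_=False` but their networks are
  essentially final (the objective trace is flat).
- Edge precision is bounded by TFA collinearity: when two planted programs
  correlate highly, target assignment between them is not identifiable and
  precision drops while sign agreement on recovered edges stays high.
- The binomial cluster null treats genes as exchangeable and symbols as
  independent; it is a screening statistic, not a calibrated genome-wide
  error rate.
- Window-level mining (`min_window` set) prunes dominated clusters by
  pairwise comparison, which is quadratic in the number of candidates —
  fine at desk scale, not tuned for genome-scale window scans.
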