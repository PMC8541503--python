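# Methods

## The model

`mmrisk` trains and applies an RNA-seq prognostic risk score for multiple
myeloma cohorts. The procedure has four stages.

**1. Normalization.** Raw counts are scaled by median-of-ratios size
factors: for each gene with strictly positive counts in every sample, the
geometric mean across samples defines a pseudo-reference; each sample's
factor is the median of its count/reference ratios over those genes. Genes
with any zero count are excluded from the reference (the strict dialect of
the method — no pseudocounts). Screening and scoring operate on
`log2(count / factor + 1)`. The log transform is a design choice: the
cutpoint selection below is invariant to monotone transforms except for the
reported cutpoint value, and log-scale cutpoints are the community
convention for expression thresholds. Genes with zero counts in ≥ 80% of
samples (`min_expressed_frac = 0.2`) are dropped before screening — a
near-constant covariate has no meaningful survival cutpoint — and the
remaining genes define the multiple-testing family.

**2. Cutpoint screening.** For each gene, the maximally selected rank
statistic finds the expression cutpoint that best separates overall
survival. Subjects receive log-rank scores `a_i = δ_i − Ĥ(t_i)` (event
indicator minus the Nelson–Aalen cumulative hazard at the subject's time;
the scores sum to zero). For every distinct expression value μ whose
low-group fraction lies in `[minprop, maxprop] = [0.1, 0.9]`, the linear
statistic `S_μ = Σ_{x_i ≤ μ} a_i` is standardized under the permutation
null,

    Z_μ = (S_μ − m·ā) / sqrt( m(N−m)/(N(N−1)) · Σ(a_i − ā)² ),

and the gene's statistic is `M = max_μ |Z_μ|` with the cutpoint at the
argmax (ties → smallest μ; the cutpoint is the largest value in the low
group, so membership is `x ≤ cutpoint`). Because the cutpoint is chosen to
maximize the separation, the naive normal p-value is optimistic; the
selection-adjusted p-value uses the Lausen–Schumacher improved Bonferroni
approximation

    p ≈ 4φ(b)/b + φ(b)(b − 1/b)·log[ t₂(1−t₁) / ((1−t₂)t₁) ],

where (t₁, t₂) is the quantile window. The raw asymptotic formula is
non-monotone for small b, where it is vacuous; `pvalue_adjusted` returns its
monotone non-increasing envelope, floored at the single-split two-sided
normal p-value and clipped to [0, 1]. In the significance range the envelope
equals the raw formula. A plain Bonferroni correction over the candidate
cutpoints is available as a conservative fallback (`pmethod =
"none_bonferroni"`). Monte-Carlo calibration (null covariate, n = 100,
2000 replicates; see the acceptance suite) puts the empirical type-I error
at nominal 0.05 in the 0.03–0.05 range.

**3. Signature construction.** Per-gene adjusted p-values are corrected
across the screened family by Benjamini–Hochberg; genes with q < α = 0.05
form the signature. Each selected gene's weight is the log hazard ratio β
from a univariate Cox fit of the *dichotomized* above-cutpoint indicator —
not the continuous expression — so the direction label, the cutpoint and the
weight are mutually consistent by construction (β > 0 ⇔ high expression
adverse). A patient's risk score is

    score = Σ_i w_i β_i,   w_i = +1 if x_i > cutpoint_i else −1,

bounded by ±Σ|β_i|; higher score means higher risk.

**4. Stratification and validation.** The maximally selected rank statistic
is run once more with the score as covariate to find the cutoff with the
largest overall-survival separation; patients with score > cutoff form the
high-risk group, compared by Kaplan–Meier curves and the two-group log-rank
test. For an independent cohort the counts are normalized with that cohort's
own size factors and scored with the trained cutpoints and betas. The score
cutoff can be transferred from training (honest external validation) or
refit by maxstat on the validation scores (default; robust to cross-cohort
score-scale shifts but with an optimistic log-rank p, since the cut is again
optimized). Both policies are exposed because cross-cohort scale handling is
genuinely underdetermined; refitting is the default on the view that the
published validation split behaves like an optimized cut.

Missing signature genes in a new cohort contribute 0 to the score, tolerated
up to 10% of the signature (`max_missing_frac`); beyond that the cohorts are
deemed incomparable and scoring fails loudly.

## Survival machinery

Kaplan–Meier, the log-rank test, and Cox proportional hazards are
implemented in `mmrisk.survival`. Ties between an event and a censoring at
the same time follow the standard risk-set convention (the censored subject
stays at risk). The Cox model maximizes the partial likelihood by
Newton–Raphson with step-halving; convergence when the score's maximum
absolute entry or the relative log-likelihood change falls below 1e-9
(≤ 50 iterations). Tied event times use Breslow's approximation by default —
chosen so the score test at β = 0 for a binary covariate reproduces the
log-rank statistic exactly on untied data, an identity the test suite checks
to 1e-8 — with Efron's correction available. Reported p-values are Wald
(per-variable HR + p is the reporting convention for clinical Cox tables). A
monotone likelihood (perfect separation) is flagged via `converged = False`
with a diagnostic rather than an exception. In score-versus-covariate
analyses the score enters Cox as the binary high/low indicator by default
(matching how such scores are reported clinically); the continuous score is
available via `score_as="continuous"`.

Wilcoxon rank-sum comparisons use exact enumeration when both groups have
≤ 12 untied observations and the tie-corrected normal approximation (no
continuity correction, so symmetric data give p = 1 exactly) otherwise.
Drug-response correlations are Spearman by default — invariant to the
log-scale choice for IC50 — with Pearson also provided for linear reporting.

## The synthetic cohort generator

`mmrisk.simulate` generates cohorts with the statistical structure the
pipeline assumes, plus ground truth for recovery tests. Defaults (the
generator's study conditions, fixed once):

| parameter | default | meaning |
|---|---|---|
| `n_samples` / `n_genes` | 300 / 1000 | cohort and panel size |
| `n_prognostic` | 30 (20 adverse / 10 protective) | planted genes, 2:1 split |
| `effect_log_hr` | 0.9 | per-gene hazard effect of the threshold indicator |
| `planted_cutpoint_quantile` | 0.5 | latent threshold location |
| `axis_loading` | 0.6 | correlation of planted genes with the risk axis |
| `baseline_hazard` | ln 2 / 2190 d⁻¹ | exponential baseline, median OS ≈ 6 y |
| `censoring_fraction` | 0.35 | administrative-censoring target |
| `latent_sd`, `dispersion`, `libsize_sigma` | 1.0, 0.15, 0.25 | expression noise model |

Each gene has a log-normal latent expression level observed through
negative-binomial counts with per-sample library sizes. Planted genes load
on a per-patient latent **risk axis** u ~ N(0,1) — adverse genes positively,
protective genes negatively, with correlation 0.6 and unchanged marginal
variance. This mirrors real prognostic signatures, whose genes tag a shared
biology (proliferation, MYC, epigenetic state) rather than thirty
independent mechanisms; it is also what makes per-gene *marginal* screening
effects detectable at all. With fully independent planted genes the other
genes act as a large unobserved frailty that attenuates every marginal
hazard ratio — at these sample sizes nothing reaches significance — so the
correlated axis is a structural requirement of the design, not a tuning
knob. The hazard itself is threshold-shaped, mirroring the dichotomized
score construction:

    h_j(t) = h₀ · exp( Σ_i β_i · 1[z_ij > c_i] )   (centered indicators),

with a linear-effect mode (`linear_effects=True`) for robustness checks.
Censoring combines uniform study entry with an administrative horizon τ
solved by bisection so the expected censoring fraction meets the target.
Validation cohorts redraw patients (new axis, new noise) from the same
generative law, optionally with a library-size shift; annotations multiply
the carrier odds by `link_odds` in the true high-risk group (u > 0); drug
responses are log-linear in the standardized score with the slope set from
the Pearson–Spearman relation for bivariate normals (ρ_p = 2 sin(πρ_s/6)).

**What passing tests do and do not show.** The generator reproduces
threshold effects, right-censoring, library-size variation, overdispersed
counts and a shared risk axis; it does not attempt real MM gene-level count
distributions, gene–gene correlation beyond the single axis, batch
structure, or informative censoring. Recovery results therefore demonstrate
correctness of the machinery under the assumed model, not expected
performance on any particular clinical cohort.

## Numerical choices and degenerate inputs

- Cutpoint ties (equal |Z|): smallest μ wins — deterministic output.
- Genes that are constant, or constant within the admissible quantile
  window, are skipped with a recorded reason and excluded from the BH
  family (they contribute no test).
- Zero events: log-rank returns p = 1 with a flag; maxstat raises a
  degenerate-covariate error (all rank scores vanish).
- A stratification cutoff outside the score range produces a single-group
  result with a warning and no log-rank test.
- All randomness flows from explicit integer seeds (`numpy` Generator);
  rerunning any stage with the same seed reproduces artifacts byte for
  byte.

## Known limitations

- Maxstat **cutpoint location** is weakly identified when a gene's signal is
  shared with correlated genes: |Z(μ)| is then a broad plateau and the
  argmax has heavy-tailed sampling error (mean absolute error ≈ 0.09
  quantile units at the default conditions, but individual genes can miss by
  0.2–0.3). Selection, direction and score-level results are robust to this;
  per-gene cutpoint values should not be over-interpreted. This is a known
  property of maximally selected statistics, not specific to this
  implementation.
- The refit validation policy re-optimizes the cutoff and therefore
  overstates validation significance; use the transfer policy for honest
  external validation.
- No time-varying covariates, stratified Cox, frailty models, or
  three-group risk models.
- The per-gene Cox betas come from univariate fits of dichotomized
  indicators; they are not a joint (penalized) model and inherit the usual
  dichotomization efficiency loss.
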