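# mmrisk

Prognostic risk scores from RNA-seq for multiple myeloma cohorts.

Newly diagnosed multiple myeloma is molecularly heterogeneous, and
expression-based risk scores are a standard way to identify high-risk
patients at diagnosis. `mmrisk` implements the full pipeline for building
and validating such a score from a raw RNA-seq count matrix and
overall-survival follow-up:

1. **Normalization** — median-of-ratios size factors, then
   `log2(normalized + 1)`.
2. **Per-gene cutpoint screening** — maximally selected rank statistics: for
   each gene, the expression cutpoint maximizing the standardized log-rank
   statistic `M = max_μ |Z_μ|`, with a Lausen–Schumacher selection-adjusted
   p-value, Benjamini–Hochberg corrected across genes (q < 0.05).
3. **Scoring** — each selected gene contributes its Cox log hazard ratio
   β (from the dichotomized above/below-cutpoint indicator), signed by the
   patient's side of the cutpoint:
   `score_j = Σ_i ±β_i`, with +β_i when expression is above the cutpoint.
4. **Stratification** — a maxstat cutoff on the score splits the cohort into
   high/low risk groups, compared by Kaplan–Meier curves and the log-rank
   test; trained signatures apply to independent cohorts with a transferred
   or refit cutoff.
5. **Associations** — Wilcoxon comparisons of the score across binary
   annotations (cytogenetics, mutations), Spearman correlation with drug
   response, and uni/multivariate Cox tables of score plus covariates.

A synthetic-cohort generator (`mmrisk.simulate`) produces RNA-seq-like
cohorts with planted threshold-effect prognostic genes and ground truth, so
every stage is covered by recovery and calibration tests. See
`docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
import mmrisk as mm

cfg = mm.SimulationConfig(seed=7)              # 300 patients, 1000 genes, 30 planted
counts, surv, truth = mm.simulate_cohort(cfg)

res = mm.RiskScoreModel(counts, surv).fit()
print(res.summary())

vcounts, vsurv = mm.simulate_validation_cohort(cfg, truth, n_samples=150)
val = res.validate(vcounts, vsurv, cutoff_policy="transfer")
print(f"validation: {val.frac_high:.1%} high risk, log-rank p = {val.logrank.p_value:.3g}")
```

Output:

```
RNA-seq risk signature
==========================================================
Samples:                 300
Events:                  199
Genes screened:          1000 (skipped 0)
Genes selected (q<0.05): 31  [20 adverse-high / 11 protective-high]
Score cutoff (maxstat):  -5.5291
High-risk fraction:      0.623
Log-rank p (high vs low): 8.43e-60
==========================================================
Top signature genes (by adjusted p):
gene_id cutpoint   beta      direction    p_adj
  G0921    6.369 -1.473  poor_when_low 6.72e-15
  G0264    4.876 +1.363 poor_when_high 5.21e-14
  ...

validation: 62.0% high risk, log-rank p = 3.84e-29
```

The screen recovered 31 genes, 29 of them planted: 20 where high expression
is adverse (β > 0) and 11 protective, matching the planted 2:1 partition.
The signed-β score separates survival strongly in both the training cohort
and an independently drawn validation cohort scored with the *transferred*
cutpoints, betas and cutoff. `res.signature.save("signature.json")`
serializes the trained model; `res.plot_km()` draws the Kaplan–Meier
curves.

The same pipeline runs from the shell:

```bash
mmrisk simulate --out-dir sim --seed 7
mmrisk all --counts sim/counts.tsv --survival sim/survival.tsv \
    --validation-counts sim/validation_counts.tsv \
    --validation-survival sim/validation_survival.tsv \
    --annotations sim/annotations.tsv --out-dir run
```

Artifacts (signature JSON, stratification and KM TSVs, association report)
land in `run/` together with a manifest recording the seed, package version
and input checksums.

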