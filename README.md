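# bgmm-oce

**Bayesian Gaussian mixture virtual-cohort generation with optimal
component estimation.**

Clinical studies of rare conditions — hypertrophic cardiomyopathy being
the motivating case — rarely recruit enough patients to power risk models
or *in silico* trials. `bgmm-oce` trains a generative model on a small
real cohort (a few hundred patients, a few dozen numeric clinical
features) and samples arbitrarily many *virtual patients* whose joint
distribution mimics the real one, together with a quality report
quantifying how faithful the synthetic cohort is.

## The method

The generator is a truncated stick-breaking Dirichlet-process Gaussian
mixture fitted by variational inference, with its two structural
hyperparameters chosen from the data instead of by hand:

1. **Curation.** Features with ≥ 30 % missing values or non-numeric
   content are set aside; duplicated columns are dropped (|Pearson r| ≥
   0.999 on shared rows, or casefolded Levenshtein distance ≤ 1 between
   names); outlying patients are flagged with an Isolation Forest trained
   on complete-case records; remaining missing cells are imputed by
   k-nearest-neighbour means (k = 5).
2. **Component estimation.** The curated matrix is robust-scaled
   (median / IQR per feature), embedded with the symmetric normalised
   graph Laplacian of a Gaussian-kernel m-NN affinity graph — the k
   smallest eigenpairs come from the LOBPCG block eigensolver — and
   clustered by k-means for each candidate k ∈ [2, 20]. Each partition is
   scored with the Davies–Bouldin index; the scan stops early after 5
   non-improving candidates and returns the best k as `opt`.
3. **Training and sampling.** A DP-GMM with truncation T = `opt`,
   weight concentration γ = exp(−`opt`), and Normal–Wishart priors is
   fitted by coordinate-ascent variational inference (stick fractions
   V_t ~ Beta(1, γ), weights w_t = V_t ∏_{s<t}(1−V_s)); the ELBO is
   checked to be non-decreasing at every step. P virtual patients are
   drawn from the posterior mixture and mapped back to original units.
4. **Validation.** Five indicators compare synthetic and real cohorts:
   mean |Δ coefficient of variation|, inter-feature and intra-patient
   correlation differences, a goodness-of-fit score (mean per-feature
   two-sample Kolmogorov–Smirnov statistic), and mean per-feature
   histogram KL divergence. Per-feature KDE overlay curves can be
   exported for visual checks.

Because real clinical cohorts of this kind are not redistributable, the
package ships a first-class fixture generator
(`bgmm_oce.make_clinical_table`) that emulates the target cohort shape:
648 patients × 20 continuous features organised in correlated blocks
over latent patient strata, with injected missingness, displaced outlier
rows, duplicate columns and case-twin names — all annotated so every
pipeline stage can be tested against ground truth.

## Worked example

```sh
python - <<'EOF'
import bgmm_oce as bo
from bgmm_oce.fixtures import table_to_dataframe
raw, _ = bo.make_clinical_table(bo.ClinicalTableSpec(seed=1))
table_to_dataframe(raw).to_csv("cohort.csv", index=False)
EOF
bgmm-oce run --input cohort.csv --n-virtual 1000 --db-rule min --seed 1 --out out/
```

prints

```json
{
  "opt": 5,
  "eligible_features": 19,
  "outliers_flagged": 32,
  "indicators": {
    "cv_diff": 0.006164428351386889,
    "inter_corr_diff": 0.12054181842561529,
    "intra_corr_diff": 0.011795674688056701,
    "gof": 0.04874436090225564,
    "kl": 0.048688871929879474
  },
  "report": "out/report.json"
}
```

Reading the output: of the 22 raw columns, 19 survived curation (one
40 %-missing feature, one duplicated column and one case-twin name were
excluded, with reasons in `out/curation_log.jsonl`); 32 patients were
flagged as outliers and held out of model fitting; the Davies–Bouldin
scan selected 5 mixture components — the number of latent strata the
fixture actually contains; and the 1000 virtual patients reproduce the
real cohort's dispersion to a mean cV difference of 0.006, its
patient–patient correlation summary to 0.012, and its marginals to a
mean KS statistic of 0.049 and a mean histogram KL of 0.049 nats. The
directory also holds `synthetic.csv` (the virtual cohort),
`model.json` (the posterior, reloadable with `BGMMPosterior.load`) and
`cluster_scan.json` (every evaluated k with its score).

`bgmm-oce sweep --sizes 1000:30000:1000 ...` re-samples a trained model
across virtual-population sizes and tabulates the five indicators per
size.

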