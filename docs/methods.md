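# Methods

`vocstack` implements a two-platform volatile-organic-compound (VOC)
classification and correlation pipeline for discriminating primary
sclerosing cholangitis (PSC, with or without concurrent IBD) from
inflammatory bowel disease (IBD) alone, using fecal-headspace GC-MS
profiles and a curated exhaled-breath panel. This note records the models,
the defaults and why, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Blank-based feature retention

A fecal feature is kept when

    median(c_samples) > median(c_MC-blanks) + 3 · IQR(c_MC-blanks)

with medians/IQR over biological samples and microchamber blanks
respectively, strict inequality, and missing entries excluded from all
order statistics. IQR is Q3 − Q1 with linear-interpolation quantiles (the
convention is recorded per feature in the result so it is pinned by
tests). Instrument blanks and QC runs are excluded from both sides: QC
monitors instrument performance, and the rule is defined against the
sampling-device background. A feature missing in every biological sample
is dropped with reason `all-missing`.

## Unsupervised forest screen

A random forest separates the real table from a column-wise permuted copy
(Breiman-style synthetic contrast); OOB proximities among the real rows
are embedded by principal coordinates. The reported role-separation
statistic is the **blank-side mean silhouette width** of the
biological-vs-blank partition (QC excluded) on the 1 − proximity
distance. The mean silhouette over *all* samples is intentionally not
used: biological profiles are heterogeneous by design (strong per-sample
dilution), so the overall mean is dominated by within-class spread and
says nothing about whether blanks sit in their own cluster — which is the
question the screen answers. Under the default simulator settings this
statistic is ≈ 0.75.

## Log ratios and dilution invariance

Without reliable internal standards or workable quotient normalization,
per-sample dilution is removed by expanding all p(p−1)/2 pairwise log
ratios log(x_i/x_j) (canonical orientation i < j). The ratio is computed
on the raw quotient, so a common row factor cancels exactly; with
power-of-two row scalings the cancellation is IEEE-exact and the entire
downstream chain is bitwise invariant, which the tests assert.

Missing values (detection-limit-like) are imputed per iteration as
Uniform(0.5·m_f, m_f) draws, m_f the feature's minimum observed positive
value — a standard below-LOD convention.

## Shadow-feature stability selection

Per iteration: class-wise patient subsampling (83% of the PSC class, 73%
of the IBD class; the complement is that iteration's validation set —
jointly this realizes an ≈76/24 split), one randomly chosen duplicate per
patient for the importance model, fresh imputation, ratio expansion,
shadow append, forest fit, and a "hit" for every column whose permutation
importance on the validation patients reaches ≥ 40% of that iteration's
maximum. Ratio frequencies at or below the maximum shadow frequency are
zeroed; the surviving frequencies fill a symmetric compound × compound
matrix whose column sums rank the original compounds; the final feature
set is the top-k ranked compounds (with the surviving ratios touching
them) maximizing internal-validation AUC, ties toward smaller k.

Two design choices deserve emphasis:

- **Permutation importance, computed batched.** Importance is mean
  decrease in validation accuracy under single-column permutation. All
  single-column-permuted copies are stacked and predicted in a few large
  calls; per-column predict loops are orders of magnitude slower at
  thousands of ratio columns.
- **Frozen, patient-block shadow permutations.** Iterations share most of
  the cohort, so a null feature's spurious association with the class
  label *persists* across iterations. Shadows must carry null
  associations with the same persistence and the same patient-level
  granularity (duplicates share biology), or the shadow-max threshold
  systematically understates the null ceiling. Shadow columns are
  therefore built from one per-column patient-block permutation drawn
  once per run, not reshuffled per iteration. With per-iteration
  sample-level reshuffling the measured null false-positive rate is
  several-fold higher.

## Final model, ROC and sensitivity analyses

The final classifier averages held-out class probabilities over
duplicate-safe iterations (both duplicates enter the training pool when
their patient does; duplicates never straddle the split). ROC AUC is
trapezoidal; the reported sensitivity/specificity pair is the Youden-J
operating point, as no threshold rule is otherwise implied. OOB proximity
(co-leaf frequency over trees where both samples are out of bag) from an
all-data forest is embedded by PCoA (Gower centering, negative
eigenvalues truncated to zero since 1 − proximity need not be Euclidean).

Sensitivity analyses: a water-content-only forest (bias check), AUC
restricted to severity-score quantile strata of the positives, and a
permutation pseudo-F test of a numeric covariate on the proximity
distance matrix (distance-based redundancy form: F = tr(HGH) /
[tr(RGR)/(n−2)] with H the covariate hat matrix and G the Gower-centered
squared distances; p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)). This
permutation test replaces a regularized-MANOVA step whose internals are
not fully specified in the source literature; it addresses the same null.

## Proximity stacking

Platform fusion happens at patient grain (fecal duplicate rows/columns of
the proximity are averaged; breath has one sample per patient):
P(w) = w·P_fecal + (1−w)·P_breath. A final forest is trained on the
principal-coordinate embedding of 1 − P(w), keeping components that
explain ≥ 90% of the positive eigenvalue mass; w is grid-searched (default
0…1 step 0.05) on internal-validation AUC with ties toward 0.5. The split
stream is deliberately shared across the grid (common random numbers), so
AUC(w) comparisons are low-variance and identical platforms give exactly
constant AUC in w.

A property worth knowing: with one informative and one pure-noise
platform, AUC(w) collapses at the noise extreme but is nearly flat for
w ≳ 0.3 — the forest on the embedding simply ignores noise axes. The
optimizer therefore reliably avoids the noise end but need not
concentrate at the informative extreme; tests assert the former.

## Cross-platform correlations

Because fecal ratios only exist after randomized imputation,
correlations are iterated: per iteration, CCA (direct implementation:
standardize, whiten by inverse-sqrt covariance, SVD; ridge 1e-6 with a
warning when a covariance is rank-deficient) with recursive elimination
of the feature with the smallest absolute structure loading until the
permutation p-value of the first canonical correlation reaches α = 0.05
(or both sides reach 2 features, flagged). A chi-square screen
(Yates-corrected 2×2 of selection counts, real vs row-permuted pairing)
keeps features selected significantly more often on real data; final
canonical and univariate Pearson correlations are averaged on the
Fisher-z scale, with mean p, the fraction of significant iterations, and
BH adjustment of the averaged univariate p matrix. Blood association uses
the same machinery against the four liver markers (ALP, AST, ALT,
bilirubin), restricted to the PSC-class population; constant blood
columns are dropped with a warning, and a screen that keeps fewer than
two features on a side falls back to the full set (CCA needs a
multivariate side).

Note that within one cohort the iterations differ only through imputation
draws: per-iteration p-values are strongly correlated and a single run's
`frac_significant` is near 0 or 1 under the null. Calibration statements
("significance rate ≈ α") are therefore made across independent cohorts,
and that is how the tests check them.

## Synthetic cohort generator

The generator emulates the study design; its defaults are the study
conditions and are not tuned per experiment:

| parameter | default | rationale |
|---|---|---|
| patients (PSC / PSC-IBD / IBD) | 8 / 16 / 49 | cohort table |
| duplicate_rate | 0.9 | 67 of 73 fecal patients measured twice |
| water means (%) | 74.02 / 80.33 / 73.79, SD 6 | cohort table |
| n_features_fecal | 24 | desk-scale stand-in for the untargeted space (count not published); keeps p(p−1)/2 tractable |
| n_features_breath | 20 | curated breath panel size |
| n_markers | 5 | ≈ 20% of features discriminatory, similar to 18/62 |
| effect_size | 2.0 (log scale) | "strong planted marker"; per-marker effects N(2, 0.5) |
| bio_sd / meas_sd | 1.0 / 0.3 | patient biology dominates duplicate noise |
| dilution_sd | 1.0 | the heterogeneity that motivates log ratios |
| missing_rate | 0.10 | below-LOD censoring, biased to low-intensity cells |
| blank_leak | 0.15 | contamination fraction removed by the blank rule |
| blood_link_strength | 0.9 | strong breath–blood, weak fecal–blood linkage |

Intensities are log-normal (positive, right-skewed, like GC-MS peak
areas). Duplicates share patient-level biology and differ by measurement
noise and their own dilution factor, so planted effects are consistent
within a patient. Blood markers are linear in designated breath markers
plus noise and elevated in the positive class. Breath tables are complete
(curated panel); missingness applies to the fecal platform. The generator
does **not** emulate chromatographic peak shapes, retention-time drift,
co-elution, batch effects over time, or correlated marker blocks — so
passing tests demonstrate the statistical machinery behaves correctly
under the assumed data-generating process, not that the biological
findings of any particular cohort are reproduced.

## Problem sizes used by tests and the acceptance script

The published procedure runs 500 stability iterations and 5000
correlation imputations. The packaged experiments keep the cohort design
fixed and scale compute knobs: stability selection 15–40 iterations with
100–200 trees, model evaluation 20–30 iterations, fusion grids of 11–21
weights with 12-iteration inner validation, correlation runs with 60–199
permutations. Null calibration uses 20 zero-effect cohorts (shadow
thresholding), 10 label permutations (chance-level AUC), and 40
independent cohorts (significance rate); recovery and fusion use the
default planted-marker conditions. These sizes are the package's choices
for desk-scale reproduction; all seeds are explicit.

## Known limitations

- The selection-frequency calibration depends on the frozen patient-block
  shadow construction; with very few patients (< ~10 per class) the
  shadow-max ceiling is coarse.
- The fused model's bridge from averaged proximities to a trainable
  feature space (PCoA embedding) is one of several defensible readings of
  "a final model on the averaged proximities"; a direct kernel method is
  an alternative not implemented here.
- RFE eliminates one feature at a time from either platform by structure
  loading; alternating or grouped elimination schemes are not explored.
- The generator's independence of non-marker features makes recovery
  experiments easier than correlated real panels would be.
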