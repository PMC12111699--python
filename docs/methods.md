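# Methods

This note records the statistical models, the generator design, the
numerical choices, and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trait derivation

Serial body weights (d 0, 1, 21, 42, 63, 84) are regressed per animal on
day with a quadratic by OLS; total gain is the fitted value at d 84 minus
the fitted value at d 0, and ADG is gain / 84 d. Using the fitted rather
than the raw initial weight treats both endpoints symmetrically and damps
scale-day measurement error; `adg_from_weights(..., use_fitted_initial=False)`
gives the raw-weight variant. Fewer than three distinct weighing days makes
the quadratic underdetermined and is an error. G:F is defined per animal as
ADG/ADFI and validated to 1e-10 whenever all three columns are supplied.

## Mixed-model engine

The only random term is sire, so the marginal covariance is
V = σ²_e (I + λ ZZᵀ) with λ = σ²_s/σ²_e. The REML criterion is profiled:
for fixed λ, β is the GLS solution and σ̂²_e = RSS_GLS/(n − p) in closed
form, leaving a one-dimensional criterion in λ. That criterion is evaluated
on {0} ∪ logspace(10⁻⁶, 10³, 61) and refined by golden section (relative
tolerance 1e-8 on the bracket); a refinement that fails to shrink the
bracket returns the best grid point with `converged=False`. All per-λ
algebra runs in the thin-SVD basis of Z, so one criterion evaluation is
O(np) and a batched variant shares the design across thousands of gene
responses with per-column λ optima (vectorised golden section). At λ = 0
the fit reduces exactly to OLS, which is both a tested invariant and the
boundary behaviour when the sire variance estimate hits zero.

Design matrices use reference-level dummy coding (first lexicographic level
dropped, for determinism). Columns are screened by a greedy rank-revealing
sweep — a column enters only if it raises the numerical rank — so exactly
collinear terms (e.g. a pen partition identical to breed, or a constant
covariate) are dropped and recorded rather than crashing the fit; this
plays the role of the dependency check that precedes model fitting.

Wald p-values use t = β/SE with n − rank(X) denominator df. This is
deliberately simple (no Satterthwaite correction); at the herd sizes this
package targets (n ≈ 60, 12 sires) the type-I error of the scan measures
at its nominal level (tested by simulation), and the df rule is documented
rather than hidden.

Model R² for a mixed model has no single definition; here it is the
squared Pearson correlation between the observed trait and the conditional
fitted values Xβ̂ + Zû (BLUPs included), with the marginal variant
(fixed effects only) also exposed. The hematology scan reports each
parameter's R² increment over the breed+pen+age+sire baseline, in absolute
units; multiplied by 100 they can be read as percentage points of variance.

## Count preprocessing

The low-expression filter removes a gene if its mean count is below 10 OR
it is zero in more than 80% of samples. Whether the published rule was OR
or AND is ambiguous from its wording; OR (remove on either criterion) is
the conservative standard and the default, the AND variant is a flag, and
per-criterion removal counts are logged so either reading is auditable.

Size factors are the median-of-ratios estimator: per-gene reference = the
geometric mean across samples over genes with all-positive counts; the
factor of a sample is the median of count/reference over those genes (the
median is taken on the ratio scale, which matters when the gene count is
even). Factors are not rescaled afterwards. The log transform for PCA and
DE is log2(count/factor + 1); the PCA input convention (log2, gene-centred,
not unit-scaled, lowest-variance 10% of genes dropped before centring) is
config-switchable since the upstream convention is not fixed by the design.

Sample QC flags points outside a confidence ellipse in the PC1/PC2 plane:
squared Mahalanobis distance from the sample mean under the sample
covariance, cut at the χ²(2) quantile of the chosen level (default 0.985).
The χ² ellipse was chosen over a t-distribution ellipse because it is
closed-form and parameter-free; under bivariate normality the flag rate
converges to 1 − level (tested at n = 10,000). PCA signs follow a fixed
convention (largest-magnitude score positive per component).

## Differential expression and degrees of freedom

Both the trait and every gene are residualized against the same design —
breed, pen fixed; sire random; age plus six cell-composition covariates —
and conditional residuals (y − Xβ̂ − Zû) are correlated gene-by-gene.
Cell composition enters as the five leukocyte fractions of WBC plus the
absolute RBC count: a red-cell count has no meaningful share of the
leukocyte total, while the five differentials are exactly compositional
(they sum to WBC by instrument arithmetic). Marginal residuals are
available via configuration.

The p-value for the correlation uses t = r·√(df/(1−r²)). The default df is
**n − rank(X) − 1**, not the textbook n − 2: both residual vectors are
confined to the (n − rank(X))-dimensional orthogonal complement of the
fixed-effect design, so under the null their correlation behaves like one
computed from n − rank(X) exchangeable observations. With n = 59 samples
and a rank-13 design this is the difference between a null correlation SD
of 0.149 and the 0.132 that n − 2 would assume — enough to push the
realized FDR of the n − 2 rule to several times its nominal level in the
package's own null simulations. `df_method="simple"` reproduces the common
n − 2 practice for comparison; the package defaults to the calibrated
rule. A permutation test that shuffles residual entries matches the
*simple* p (shuffling breaks the subspace alignment), which is why naive
permutation does not diagnose the issue.

Reg is reported as the correlation coefficient itself: after
residualization both vectors are on arbitrary scales, and the standardized
slope equals r.

BH adjustment is the step-up rule adj_(i) = min(1, min_{j≥i} m·p_(j)/j)
with m equal to the number of genes tested after filtering; an `m_total`
override lets a printed shortlist be adjusted against the full test count.
Genes whose residuals are numerically constant (below 1e-10·√n) are
reported with r = 0, p = 1 and a degenerate flag rather than dropped.

## Synthetic-data generator

The generator's defaults are the trial conditions: 61 animals, 3 breeds,
12 sires nested in breed (balanced within one animal), 4 pens, age ~
N(270, 15²) days, 34,000 genes of which ~45% pass the expression filter,
20 planted genes at partial correlation 0.6 with G:F, NB dispersion 0.1,
log-normal library factors (σ = 0.25). Pen count and age spread are not
fixed by the design being emulated and are exposed in the config.

**CBC panel.** The five differential counts are independent log-normals at
the published herd means/SDs and WBC is their exact sum. (log RBC, log MCV)
are bivariate normal with the negative correlation implied by the HCT SD
anchor — biologically, animals with larger red cells have fewer of them —
and HCT = RBC·MCV/10 times an analytic calibration constant (~0.993) that
recenters its mean on the anchor; the published moment set is not exactly
consistent with the instrument identities, and the constant absorbs that
sub-percent slack. MCHC is drawn at its anchor and HGB := MCHC·HCT/100, so
the MCHC identity holds exactly; MCH = 10·HGB/RBC carries its own ~0.6%
calibration constant. RDW, PLT, MPV are independent log-normals. All
anchored means converge to their targets (tested at n = 5000 within 3·SE);
an anchor SD of zero degenerates to the constant mean.

**Traits.** ADG = mean + sire effect + linear CBC effects + noise, with the
sire effects drawn at variance σ²_s (default 0.01 (kg/d)²) and centred so
the herd mean is exact; residual variance is set so the total matches the
anchor SD². ADFI is built the same way with the same intraclass share; G:F
is the per-animal ratio. Weights follow BW = w0 + b·d + c·d² with shared
curvature fitted to the herd-mean weights and per-animal slope chosen so
the latent 84-d gain is exactly 84·ADG, plus 3 kg measurement noise at
each weighing.

**Counts.** log μ_gs = base_g + log sf_s + γ_g·comp_s + δ_g·t_s, NB-sampled
with variance μ + αμ² (α = 0 gives Poisson). base_g is log-normal with
log2-mean ~ N(3, 2.5), chosen so roughly the observed fraction of genes
survives the mean ≥ 10 filter. A configurable fraction of genes (default
30%) is tied to one standardized cell-composition score (leukocyte
fractions or RBC); planted genes are additionally tied to the standardized
design-independent component of the target trait (for G:F, the first-order
combination of the ADG and ADFI noises), with δ_g calibrated per gene from
its delta-method log-count noise (1/μ_g + α) so the planted partial
correlation hits its target. Planted genes are drawn from genes with
baseline mean ≥ 50 so counting noise does not dominate. The ground-truth
object records planted ids, directions, per-gene confounder components,
library factors and the true variance components for recovery scoring.

What the generator does **not** emulate: the real herd's full CBC
correlation structure beyond the identities above, read-level artifacts
(GC, length, mappability), hemoglobin-transcript content, breed-specific
expression differences, and any genetic architecture beyond a single
additive sire term. Passing tests therefore certify the statistical
machinery under a faithful but idealized data-generating process, not
performance on any particular real herd.

## Problem sizes used in tests and acceptance

Simulation-based checks use 20 seeds at the trial's retained sample size
(n = 59) with 2,000-gene panels for DE calibration and power; REML recovery
uses n = 2,000 animals across 100 sires; ellipse calibration uses 10,000
bivariate-normal scores; the scan's type-I error uses 400–1,000 single-model
replicates; the full default-size pipeline (34,000 genes) runs once in the
acceptance script. These sizes give stable Monte-Carlo estimates while
keeping the whole suite in the low minutes on one core.

## Known limitations

- One random effect only; no crossed or nested random terms, no GLMM.
- Wald t with n − rank(X) df, no Satterthwaite/Kenward–Roger — p-values in
  the scan are mildly approximate at small sire counts.
- The DE test is a correlation on residuals, not a count-model test; no
  shrinkage of dispersions or effect sizes.
- The ellipse QC only looks at the first two PCs.
- Conditional residuals absorb BLUP shrinkage, so the effective-df rule is
  a first-order correction; it measures as slightly conservative in the
  package's null simulations.
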