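# Methods

## Model and assumptions

All analyses operate on two-sample GWAS summary statistics: per-variant
association estimates (β̂, se) for an exposure from one sample and for an
outcome from a second, non-overlapping sample. A variant j is a valid
instrument when it is (i) associated with the exposure, (ii) independent
of exposure–outcome confounders, and (iii) associated with the outcome
only through the exposure. Under these assumptions the per-variant Wald
ratio r_j = β̂_Yj / β̂_Xj estimates the causal effect, and the estimators
combine the ratios:

* **IVW.** β̂ = Σ w_j r_j / Σ w_j with w_j = se(r_j)⁻² and first-order
  ratio SEs se(r_j) = se_Yj / |β̂_Xj| (the exposure-side term is ignored
  by default; a second-order correction is available by flag). The
  fixed-effect SE is (Σ w_j)^(−1/2); the multiplicative random-effects
  model — the default — multiplies it by max(1, √(Q/(n−1))), where
  Q = Σ w_j (r_j − β̂)² is Cochran's heterogeneity statistic. The floor
  means the random-effects SE never falls below the fixed-effect SE.
  P-values use the normal reference.
* **MR-Egger.** Weighted regression of β̂_Y on β̂_X *with* an intercept,
  weights se_Y⁻², after orienting all rows so β̂_X ≥ 0. The slope is a
  pleiotropy-robust effect estimate under the assumption that pleiotropic
  effects are independent of instrument strength; the intercept estimates
  the mean directional pleiotropic effect. The slope SE uses the same
  multiplicative floor as IVW; the intercept test keeps the plain WLS
  t-statistic (t on n−2 df), which is exactly calibrated under the null —
  the floored variant is conservative by construction and is therefore
  not used for the pleiotropy test.
* **Weighted median.** The inverse-variance-weighted 50th percentile of
  the ordered ratios, interpolating linearly between the two order
  statistics whose centred cumulative weights bracket probability 0.5.
  Consistent when ≥ 50% of the total weight comes from valid
  instruments. Its SE is a parametric bootstrap: each (β̂_X, β̂_Y) is
  resampled from Normal(β̂, se), the median recomputed, and the SD taken
  across draws (default 1000; the seed is mandatory).
* **Multivariable MR.** With K exposure-association columns X and
  outcome associations y, weighted least squares of y on X without
  intercept (weights se_Y⁻²) gives each exposure's direct effect
  conditional on the others; SEs use the multiplicative floor and t(n−K)
  reference. The Egger variant adds an intercept after orienting rows on
  one exposure. The robust median variant minimizes the weighted sum of
  absolute residuals (rows scaled by 1/se_Y; solved exactly as a linear
  program). MR-Lasso augments the WLS objective with per-instrument
  intercepts γ_j penalized by λΣ|γ_j| (exposure effects are never
  penalized); instruments with γ_j = 0 are "valid", and λ is chosen as
  the largest grid value whose valid-set heterogeneity Q stays below the
  upper-5% chi-square quantile on (n_valid − K) df. The full λ path is
  always returned for audit.
* **Mediation.** With β1 the total exposure→outcome effect (univariable,
  estimated after removing exposure instruments associated with the
  mediator at a configurable threshold, default 5×10⁻⁸), β2 the
  exposure→mediator effect, and (α1, α2) the multivariable direct
  effects, the indirect effect is α2·β2 with delta-method SE
  √(α2²se_β2² + β2²se_α2²), and the proportion mediated is (α2·β2)/β1.
  Its CI is delta-method on the ratio (treating components as
  independent) or a parametric bootstrap of all four estimates. All
  arithmetic stays on the log-odds scale for binary outcomes; odds
  ratios are exp-transforms applied at report time only. A proportion
  outside [0, 1] is reported and flagged "inconsistent mediation", never
  truncated; β1 = 0 leaves it undefined.

## Instrument selection

The QC pipeline is significance → exclusion list → LD clump → strength:
strict P < 5×10⁻⁸; greedy clumping that repeatedly indexes the
smallest-p unselected variant and discards anything with r² > 0.001 to a
retained index (ties in p broken lexicographically by id, making the
result order-independent); per-variant F = (β̂/se)² with F < 10 removed.
LD is always caller-supplied as an explicit r² matrix — the package
never computes LD from genotypes, keeping LD assumptions auditable and
the pipeline offline. Variants absent from the LD matrix are retained
and logged. Instruments missing from the outcome GWAS can be replaced
from a local proxy table (best proxy with r² ≥ 0.8 present in the
outcome, effects re-oriented onto the target's effect allele).
Confounder screening is a user-supplied exclusion list rather than a
live database query, so runs are reproducible. Every removal is recorded
in a selection log that partitions the input ids.

## Harmonization

The exposure table's effect allele defines the orientation. Outcome
records with matching allele pairs are copied; swapped pairs get a
negated beta; strand-complement readings are folded onto the same rules.
Palindromic (A/T, C/G) variants are dropped by default; the opt-in
`infer_by_eaf` policy orients them by allele frequency when both tables'
EAFs fall outside the ambiguity band [0.42, 0.58] (same side of 0.5 ⇒
same allele, opposite sides ⇒ swap). Indels and multi-allelic tokens are
rejected at parse time. Harmonization is idempotent, and re-orienting
the exposure table (swap alleles, negate betas) leaves every downstream
estimate unchanged.

## Multiple testing

Endpoint-level significance uses a Bonferroni threshold α/m; p-values
between α/m and α are tiered "suggestive", at or above α "null". m
defaults to the number of endpoints actually analyzed and is
configurable, since published analyses sometimes divide by a different
count than the number of endpoints they enumerate.

## Synthetic data

The generator emulates the summary-statistic structure of a real
two-sample study directly — no individual-level genotypes. True
instrument effects γ_j ~ Normal(0, gamma_sd²) are kept only when the
*observed* association would pass P < 5×10⁻⁸ at the panel's sampling SE
(rejection sampling, mimicking instrument discovery and its winner's
curse); observed effects add independent Normal(0, se²) noise per panel,
enforcing two-sample independence. Pleiotropy adds a per-variant outcome
offset (balanced: zero-mean; directional: mean μ). The mediation design
links three traits via exposure →(θ_xm)→ mediator →(θ_my)→ outcome plus
a direct path θ_direct, so exposure instruments carry mediator
associations θ_xm·γ_j and outcome associations (θ_direct+θ_my·θ_xm)·γ_j,
mediator instruments carry θ_my·δ_j, and the true proportion mediated is
θ_my·θ_xm/(θ_direct+θ_my·θ_xm). Defaults mirror the motivating study
design: 49 exposure instruments at se 0.01 (a ~500k-sample biobank GWAS
of a binary trait), 4 mediator instruments at se 0.03 (a ~3.6k-sample
cytokine GWAS), outcome se 0.05 (a disease-endpoint GWAS), instrument
effect scales gamma_sd 0.1 / delta_sd 0.15. Optional extras: scrambled
allele reporting (random swaps and strand flips) to exercise
harmonization, and block-diagonal LD matrices for clump testing.

What the generator does **not** model: LD between instruments beyond the
block structure, sample overlap between the two GWAS, non-collider
selection effects, allele-frequency-dependent effect sizes, and
individual-level nonlinearity. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated
summary-level model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

* Exact-fit Egger regressions (weighted residual sum of squares
  numerically zero) make the t-ratio 0/0; the implementation falls back
  to the unscaled fixed-effect SEs and tests the intercept against zero
  directly (p = 1 when it is numerically zero, 0 otherwise).
* The weighted-L1 (median) MVMR fit is solved exactly with the HiGHS LP
  solver rather than iteratively reweighted least squares, so ties and
  flat objective regions resolve deterministically.
* MR-Lasso is minimized by alternating a WLS solve for the exposure
  effects with per-instrument soft-thresholding (the objective is
  convex, so alternation reaches the joint minimum); γ entries below
  1e-9 count as zero; the default grid spans the fully-penalized λ down
  three decades in 40 geometric steps.
* Clumping tie-breaks and the deterministic JSON writer (sorted keys)
  make identical configs byte-identical end to end.
* A single instrument degrades IVW to the Wald ratio (labelled as such);
  Egger and the weighted median refuse n < 3.

## Monte-Carlo behaviour and known limitations

The replication experiments behind the acceptance checks use 500
replicates for parameter recovery and 1000 for error calibration —
sizes at which the whole suite runs in about a minute on one CPU while
leaving Monte-Carlo SEs small relative to the tolerances checked.

Two finite-sample properties are worth knowing. First, IVW recovery of
the true effect is unbiased at the default design (exposure instruments
precise relative to their effects); with a much noisier exposure panel,
regression dilution from measurement error in β̂_X would bias ratios
toward zero — real studies face the same trade-off. Second, the
mediation proportion inherits a small downward attenuation at the
default design: with only 4 mediator instruments and se_med comparable
to the exposure instruments' (collinear) mediator signals, α2's
conditional identification is weak and its estimate attenuates by
roughly 15–20%, shifting the mean estimated proportion from 1/6 to
≈ 0.148 across replicates. This is a genuine property of mediation-MR
with few, moderately precise mediator instruments, not an implementation
artifact; studies in this position should read their proportion mediated
as a mild underestimate.

The MVMR module emits no conditional F-statistics (instrument-strength
diagnostics for each exposure given the others); their absence is the
main diagnostic gap, and the attenuation just described is exactly the
phenomenon they would flag.
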