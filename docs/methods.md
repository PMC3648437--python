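# Methods

This note records the statistical procedures implemented by `seroarray`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely underdetermined.

## Data model

The pipeline's unit is the `ExperimentSet`: a features × samples matrix of
net spot signal (relative fluorescence units) with per-feature annotations
(gene symbol, control-spot flag, grid position) and per-sample metadata
(case/control group, pre/post surgical timepoint, subject, age, sex).
Net signal is foreground minus background, floored at 1 RFU so the log2
transform used everywhere downstream stays defined; the floor is
configurable. GPR-style input files are accepted loosely: any tab-delimited
file whose header row carries `Name`, `ID`, `F635 Median` and `B635 Median`
is read and other columns are ignored, because real scanner exports vary
widely. Duplicate spots printed for the same protein are collapsed at merge
time by mean net signal (median and keep-first are available); the original
acquisition software's collapsing rule is not documented anywhere we could
ground it, so the switch is explicit rather than implicit.

## Array-effect normalization

Different sera produce globally different signal levels (IgG titre,
labelling efficiency, scanner gain). These technical effects are
multiplicative, hence additive on the log2 scale, and are estimated from
control spots only so that disease biology cannot leak into the correction:

    log2 y_ij = mu + a_i + f_j + e_ij,   i = array, j = control spot

with identifiability constraints Σa_i = Σf_j = 0. The fit is iteratively
reweighted least squares with Huber weights w(u) = min(1, c/|u|), c = 1.345
(95% Gaussian efficiency), residual scale re-estimated each iteration as
MAD/0.6745, convergence when the largest coefficient change falls below
1e-8, cap 50 iterations (a warning is issued and the last iterate returned
if the cap is hit). With c = ∞ the fit reduces exactly to ordinary least
squares, which the tests exploit as an oracle; the hand-written IRLS is
also cross-checked against statsmodels' RLM on random data. The estimated
a_i is subtracted from every feature of array i. Because the model absorbs
column shifts exactly, normalization is idempotent: re-running it on
already-normalized data yields effects at solver precision.

Fitting on the full matrix instead of controls is available
(`controls_only=False`) but is not the default: with 2% of features
genuinely elevated in cases, a full-matrix location model would absorb part
of the biological signal into a_i.

Z-scores standardize each array column of the normalized log2 matrix with
the plain mean and sample SD (ddof = 1). A mean/SD standardization (rather
than median/MAD) is the documented convention here; reactivity calls use
z ≥ 3.0, boundary inclusive. Note that per-array Z-scores depend on the
composition of the whole array: features elevated in case arrays inflate
that array's SD, so a k-fold elevation only clears z = 3 when the baseline
spread is small relative to log2(k). This is a property of the statistic,
not of the implementation.

## Exact M-statistic inference

For one feature with case values x₁…x_{n₁} and control values y₁…y_{n₂},

    M = #{ i : x_i > max_j y_j }        (strict inequality)

Under the null that all n₁+n₂ values are exchangeable, {M ≥ m} is exactly
the event that the top m order statistics all lie in the case group, so

    P(M ≥ m) = C(n₁, m) / C(n₁+n₂, m),   P(M ≥ 0) = 1

computed with exact integer rationals before the final float conversion.
The formula is verified in the tests against exhaustive enumeration of all
label assignments for every group-size combination up to 6 per group. For
the 10 vs 10 discovery design the five attainable levels below 0.05 are
5.41e-6, 5.95e-5, 3.57e-4, 1.55e-3 and 5.42e-3 (m = 10…6); significance at
p ≤ 0.05 corresponds to m ≥ 4. Ties with the control maximum never count
toward M (strict inequality), so a case value epsilon below the control
maximum can never increase it. The statistic is one-sided in the
case-elevated direction, which is the direction of scientific interest
(autoantibodies elevated in disease); the pre/post comparison also reports
the mirrored statistic for post-operative trends.

The per-feature table also carries:

* **Cantelli bound** `p_cheb`: the distribution-free one-sided bound
  1/(1+z²) evaluated at the pooled-SD standardized group mean difference
  (z ≤ 0 → 1). Its two-sided Chebyshev form min(1, 1/z²) is available as a
  function. These are upper bounds on the true tail probability, hence
  conservative companions to the exact M p-value, which is treated as
  primary.
* **Fold change**: ratio of group arithmetic means on the linear
  (de-logged) normalized scale. The discovery filter keeps
  fold change > 2 (strict) and p_m ≤ 0.05 (inclusive), ordered by
  ascending p, then descending fold, then feature id — a deterministic
  total order.
* **Unpaired t** (Welch by default; pooled available) and the two-group
  one-way **ANOVA** p-value, which satisfies the F = t² identity with the
  pooled t-test and is computed as such. Zero-variance degenerate input
  with equal means returns p = 1 by convention. A summary-statistics form
  (means, SDs, ns) supports cohort-table comparisons. No multiple-testing
  correction is applied by default — the replicated analysis filtered at
  raw p — but a Benjamini–Hochberg column is available behind a flag.

The pre/post comparison (active disease vs 6 months post-revascularization)
applies the same M machinery with n₁ = n₂ = 5, whose attainable levels
include 5/210 ≈ 0.02 (m = 4) and 10/120 ≈ 0.08 (m = 3). The samples are
treated as independent groups, which is what those printed levels
correspond to; a warning is issued when the pre and post sample sets do not
pair by subject.

## Candidate prioritization

Cytobands are parsed with a strict grammar (chromosome 1–22/X/Y, arm p/q,
decimal band, optional same-arm range; range endpoints ordered distal
first) and re-serialized losslessly. Band membership treats each band label
as covering its sub-bands (25.3 lies inside 25; a locus ending at 24.2 does
not contain 21), with an arm-granularity mode that requires only the same
chromosome arm.

The cascade admits, over a differential table joined to per-gene
annotations (cytoband, DER ∈ [0,1], neurological-variant flag):

* locus stage: p ≤ p1 ∧ cytoband ∈ loci ∧ DER > der1;
* variant stage: variant flag ∧ p ≤ p2 ∧ DER > der2;

returning the union ordered by ascending p (the locus stage wins when both
apply). Genes without annotation are excluded with a warning. The set is
monotone in the thresholds (relaxing never shrinks it), which is property-
tested.

Two named configurations ship. `strict()` applies the literal thresholds
(band granularity, p1 = p2 = 0.05, der1 = 0.45, der2 = 0.6): on the
six-gene reference panel it admits only STRA13 (locus) and APP (variant),
because GPS1's array p of 0.07 exceeds 0.05, ROR1 (DER 0.586) and EDIL3
(0.484) fail DER > 0.6, and CTNNB1 at 3p21 lies outside 3p26-p24.2 at band
granularity. `panel_recovery()` (arm granularity, p1 = 0.1, der2 = 0.45)
is the relaxed setting under which the cascade reproduces the published
six-antigen panel exactly — STRA13, APP, CTNNB1, GPS1, ROR1, EDIL3, with
CTNNB1/GPS1/STRA13 entering via the locus stage. Shipping both is a
deliberate honesty measure: the literal thresholds and the published panel
are not mutually consistent, and the package asserts neither reading as
the intended one. Which three of the six count as "on linkage loci" is
likewise ambiguous at band granularity and is not asserted.

## ELISA validation

Per-antigen group comparisons are two-sided unpaired t-tests on the raw
OD(405) values (no standard-curve quantification — group contrasts do not
need it), and a covariate check runs the same test across the two levels of
e.g. sex. The panel classifier is a logistic regression on all antigens,
standardized internally to mean 0 / SD 1, fitted by Newton–Raphson IRLS
(convergence when max |score| < 1e-8, cap 100 iterations, tiny ridge
1e-10 on the Hessian for numerical safety). Complete separation manifests
as coefficient-norm divergence; a standardized coefficient exceeding 15 —
odds ratios beyond e¹⁵ per SD, i.e. saturated fitted probabilities — raises
the separation flag while the fit is still returned. Constant antigens are
dropped with a warning. The fit is cross-checked against statsmodels'
Logit in the tests.

AUC is the Mann–Whitney rank statistic with half credit for ties, which
equals the trapezoidal area under the empirical ROC (dual-method tested to
1e-12, and against scikit-learn). Confusion counts are taken at predicted
probability ≥ 0.5 (the operating point is not otherwise documented;
0.5 after standardization is the natural default), and sensitivity,
specificity, PPV, NPV and accuracy are reported both as exact fractions
and as whole percentages rounded half away from zero (34/46 → 74%,
17/29 → 59%). Metrics with a zero denominator are reported as unavailable,
never as 0. Evaluation is deliberately in-sample — apparent performance on
the fitting data, matching how such panels are usually first reported; a
k-fold estimate would be smaller and is intentionally not the default
path.

## Synthetic data

The generators are pure functions of their arguments, seed included.

`gen_array_dataset` defaults encode the discovery conditions: 8268
features of which 100 are control spots, 10 case vs 10 control arrays (the
case sera being 5 subjects × pre/post), 165 elevated features with true
folds log-uniform on [2, 85], per-feature lognormal baselines (median
300 RFU, ln-scale SD 1.0 — a typical fluorescence dynamic range),
multiplicative per-array effects 2^N(0, 0.3) on the log2 scale,
multiplicative lognormal spot noise at CV 20%, and a lognormal background
channel (median 40 RFU) so that GPR writing and re-reading round-trips the
integer-rounded net signal exactly. Control spots never receive a group
effect. Noise and effect-size parameters are exposed because none of them
are documented for the real assay; the defaults are what a practitioner
would call realistic for this platform. The injected truth (elevated ids
and folds, array effects) is serialized with every fixture.

What the generator does **not** emulate: spatial gradients and image
artifacts, print-lot and batch effects, antigen cross-reactivity,
correlated features, or heavy-tailed outlier spots. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
stated noise model, not performance on real arrays, where fold-change and
recovery operating characteristics will be worse.

`gen_elisa` defaults to the 46 vs 22 validation design over the six
panel antigens. Per-antigen standardized effects are calibrated from the
normal-theory closed form AUC = Φ(D/√2) for the optimal linear combination
of independent unit-variance Gaussians: the combined effect D solves that
equation for the 0.76 target (root-bracketed on [0, 12]) and is split
equally, d_k = D/√6. Values are Gaussian on the log scale, exponentiated
and shifted positive to mimic OD readings. The in-sample AUC of a fitted
6-parameter model on 68 samples is optimistically biased upward of the
population target by a few points, and individual seeds scatter with an
SD of about 0.04; the calibration contract is therefore stated for the
mean over seeds (±0.08), not per seed.

`gen_annotation` produces per-gene cytoband/DER/variant annotations —
uniformly random DER, random valid cytobands, 10% variant rate — and can
prepend the six-record reference candidate panel verbatim.

## Problem sizes and numerical choices

The full default pipeline (8268 × 20, normalization + all statistics) runs
in well under a second, so the tests exercise it at full size and across
multiple seeds; reduced sizes (a few hundred features) are used only where
many replicates are drawn (e.g. the 100-seed control-spot null check).
Tolerances used by the tests: solver-precision assertions at 1e-9…1e-12
for algebraic identities; ±0.05 log2 for array-effect recovery at 10% CV
and 100 control spots (≈3.5 standard errors); ±0.08 around the ELISA AUC
calibration target for the 10-seed mean. Tie-breaks in the discovery
ordering and the candidate ordering are total and documented above, so all
outputs are bit-reproducible for a given config and seed.

## Known limitations

* The exact M p-value assumes exchangeability and no ties; signals are
  continuous enough in practice that ties only arise from the integer RFU
  floor at very low signal.
* Controls-only normalization assumes the control spots share the arrays'
  technical scale and are reactivity-free; designating too few or
  contaminated controls degrades a_i.
* The Cantelli column is a bound, not a calibrated p-value, and is
  intentionally conservative.
* In-sample classifier metrics overstate transferable performance; use the
  k-fold option for an honest generalization estimate.
* DER scores are consumed as given; deriving them from expression corpora
  is out of scope, as are pathway/network enrichment analyses.
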