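# Methods

## Study structure and data model

The analysis assumes a repeated-collection design: each donor gives blood
once per week for three weeks ("season"), three seasons per year, and each
collection is split across four radiation conditions — sham control (0 Gy),
X-rays, alpha particles and a 1:1 mixed beam — at total doses of 0.5, 1 and
2 Gy, the control serving as the shared 0 Gy point of all three dose
responses. Raw data enter as two long-format CSV tables (one row per
technical-replicate Ct measurement; one row per scored metaphase). Layouts
are deliberately minimal and not restricted to this design: any dose grid,
replicate count or block structure parses, and `validate_design` reports —
rather than rejects — incomplete blocks.

## Quantification

**qPCR.** Technical replicates are averaged per (sample, target); replicate
scatter above 0.5 cycles raises a QC flag (a common qPCR heuristic; flags
never exclude data). ΔCt = mean target Ct − mean 18S reference Ct; net
level = 2^−ΔCt; fold change = 2^−ΔΔCt against the ΔCt of the same
collection's 0 Gy control. No amplification-efficiency correction is
applied — the pure 2^−ΔΔCt model is the method under study. Averaging
replicates before or after differencing is equivalent for mean aggregation
with equal replicate counts (asserted in a test).

**Aberrations.** The scoreable signal on Giemsa-stained preparations where
structural aberration typing is impossible is the count of objects
(chromosomes + fragments) per metaphase in excess of the diploid 46;
hypodiploid cells contribute zero, not negative. Frequencies are per 100
cells; 50 metaphases per dose point is the study standard.

## Dose–response fits

Fold changes are fitted per collection to `Y = 1 + s·D` (intercept fixed at
1 because the response is normalised to the control). The closed form is
`s = Σ xᵢ(yᵢ−1)/Σ xᵢ²`, with residual variance on n−1 degrees of freedom
and `se(s) = sqrt(residvar/Σx²)`. Aberration frequencies are fitted to
`Y = a + s·D` by ordinary least squares (n−2 df), unweighted by metaphase
count. The grouped table-level fits use the identical formulas
vectorised; unit tests assert bit-level agreement with the per-group
operations, and the anchored closed form is validated against a
brute-force one-parameter SSE minimiser.

## Additivity, synergy, RBE

For linear responses with a shared baseline counted once, simple effect
additivity at a 1:1 dose split gives an expected mixed-beam slope equal to
the mean of the component slopes; generally `f·s_X + (1−f)·s_α` for X-ray
share `f`. The weekly synergy ratio is `s_MB / s_EMB`, encoded undefined
(not an error) when the expected slope is non-positive; negative observed
slopes yield negative ratios, which are reported as such.

Two pooled synergy estimators are computed and labelled distinctly:

- **mean of weekly ratios** — the descriptive statistic of the weekly heat
  table and seasonal summaries. Because the noisy expected slope sits in
  every denominator it carries a small upward (Jensen) bias of order
  Var(ŝ_EMB)/s_EMB², about 1% at this study's noise levels.
- **ratio of mean slopes** — weekly-mean MB slope over weekly-mean EMB
  slope per endpoint, averaged over endpoints; the consistent estimator of
  a shared multiplicative interaction factor, used for parameter-recovery
  checks.

RBE is the slope ratio against the same week's X-ray slope; dose-to-effect
is `target/s` (default target 10 aberrations per 100 cells, an induced
effect above the free-intercept background); the dose equivalent of a
mixed exposure is `Σ doseᵢ·RBEᵢ`. All Table-1-style summaries are means ±
sd over weekly values (9 per donor, 18 pooled), with undefined weekly
values dropped and counted. Printed tables round half-away-from-zero to
two decimals; full precision is kept internally. Note that a mean of
weekly slope *ratios* (RBE, synergy) exceeds the corresponding ratio of
mean slopes whenever the denominator varies — both are reported, only the
descriptive one mirrors the conventional table layout.

## Statistics

Cohen's d uses the (n−1)-weighted pooled sd (two-sample) or the sample sd
(one-sample vs a reference), with magnitude classes small ≤ 0.5 < medium
≤ 0.8 < large < 1.3 ≤ very large on |d|. Slope-set comparisons (MB vs EMB)
are two-sided pooled-variance t-tests on the weekly slopes, with a paired
option; seasonal ratio summaries pool all endpoints × weeks of a
donor-season and test the mean against the additivity value 1. A
zero-variance sample degenerates the one-sample test to an exact equality
check (p = 1 or 0). One-way ANOVA computes the between/within
sum-of-squares decomposition directly so that pairwise contrasts can reuse
the within-group mean square (df = N−k); each contrast is Šídák-adjusted,
`p_adj = 1 − (1−p)^m`, with m = contrasts actually drawn, and annotated
with d and the star convention 0.0332/0.0021/0.0002/0.0001. The commercial
fitted-curve slope comparison this replaces is operationalised as the
t-test on weekly slopes, since weekly fits are the replicate unit
everywhere else.

Heat-table bins default to (−∞, 0.75, 0.9, 1.1, 1.35, 1.75, ∞) — a display
convention chosen for contrast around 1, fully configurable.

## Alternative-transcript analysis

Per collection and primer-pair target, irradiated net levels are averaged
over 0.5–2 Gy (controls use 0 Gy), and variant ratios are formed in the
fixed orientations FDXR PP1:PP2, CDKN1A V1:V4, MDM2 315:303/304. The
expected-MB group applies the SEA fold-change prediction to the control
net level at each dose before averaging — consistent with using one
additivity rule throughout. Groups are compared per pair by the ANOVA
machinery above (each radiation vs control plus all radiation–radiation
contrasts, m = 10 with five groups), pooled over donors and seasons or
within season subsets defined by the seasonal mean MB:EMB ratio (> 1 =
synergy season). Ratios enter untransformed by default, matching the
ratio-scale presentation; a log-ratio option exists and makes the ANOVA
invariant to orientation reversal (asserted in a test). Donor is not a
blocking factor by default.

## Synthetic studies

The generator emulates the design above: per-cell excess counts are
Poisson with mean `background + (slope/100)·dose` (background 0.02/cell);
Ct values are Gaussian around the model-implied ΔCt (replicate sd 0.15
cycles, reference Ct 15), with the reference measured once per sample so
reference noise correlates across targets as on a real plate. Fold
changes are floored at 0.05 to keep 2^−ΔΔCt positive under extreme
negative slopes.

Defaults encode the study conditions: 2 donors × 3 seasons × 3 weeks,
doses (0, 0.5, 1, 2) Gy, 50 metaphases per dose point, duplicate
reactions; aberration slopes 28 (X-rays) and 78 (alpha) per 100 cells/Gy.
Expression slopes (fold/Gy, X-ray/alpha): FDXR 2.0/5.0 and 1.5/4.0,
CDKN1A 1.0/2.5 and 0.8/2.0, MDM2 0.5/1.2 and 0.4/1.0 — chosen for the
FDXR > CDKN1A > MDM2 responsiveness ordering of these biomarker genes and
an alpha/X-ray effectiveness ratio near 2.5, matching the aberration
scale. Control ΔCt values (10–15 cycles vs 18S) put net levels in the
10⁻³–10⁻⁵ range typical for these transcripts.

Week-to-week and season-to-season biological variability is modelled as
multiplicative lognormal perturbations of the X-ray and alpha slopes,
drawn independently per endpoint and radiation (log-scale sds 0.20 and
0.25), sized so the weekly slope CV lands in the 0.3–0.4 range after
counting noise. The mixed-beam effective slope is `θ × SEA mean` of the
perturbed component slopes, so θ = 1 generates exact additivity and the
true weekly MB:EMB ratio equals θ by construction — making θ directly
recoverable. Because the perturbations are independent between radiations,
descriptive mean-of-weekly-ratio statistics (weekly RBE in particular) sit
above the corresponding ratio of means under this generator; real blood
collections likely share radiosensitivity across beams, so synthetic
weekly ratios are, if anything, noisier than real ones.

Counts can alternatively be generated in a deterministic "expected" mode
that distributes the integer-rounded expected total excess evenly over
cells; with all noise terms zero and `mean × n_cells` integral this makes
the full pipeline recover every configured slope exactly (the
noiseless-limit check uses 200 cells per dose point for that reason).
Poisson counts carry no overdispersion parameter; alpha-track clustering
would motivate a negative-binomial extension, left out of scope.

## Problem sizes and checks

The test suite validates the numerical core against independent oracles
(bisection on the SSE derivative for the anchored fit; normal equations
for OLS; sum-of-squares decomposition and scipy for ANOVA; permutation and
t-CDF oracles for the t-tests) and the estimation pipeline by Monte Carlo:
interaction-factor recovery uses 200 replicate full studies per θ ∈
{1.0, 1.5}, asserting that the mean ratio-of-mean-slopes estimate covers θ
within its 95% Monte-Carlo interval; group-comparison calibration uses 200
replicate null and shifted datasets (18 timepoints per group), asserting
the flagged-contrast rate stays within the nominal 0.0332 level under the
null and exceeds 90% power for a 2-sd alpha-group shift. The acceptance
script repeats the recovery at 150 replicates per θ.

## Known limitations

- Linear fits only; responses that flatten at 2 Gy (alpha aberrations) are
  deliberately not given a quadratic term, matching the analysis design.
- The excess-over-46 score cannot distinguish fragment types and
  undercounts complex aberrations.
- No isobologram/envelope-of-additivity construction for non-linear
  endpoints; SEA on the slope scale is the only additivity model.
- No amplification-efficiency correction or multi-reference qPCR
  normalisation.
- The generator does not model donor-level covariance between radiation
  qualities, cell-cycle effects, or qPCR efficiency drift.
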