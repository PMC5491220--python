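# Methods

## The killing score

The bacterial killing assay reads bacterial density (OD600) on the
schedule 0 h, then hourly from 5 h through the 14 h incubation horizon —
eleven reads. The killing statistic is the time at which the growth curve
crosses OD 0.3 (roughly mid-curve), obtained by inverting an ordinary
least-squares line fitted to the curve's linear phase. Three rules make
this operational:

**Growth detection.** Growth is "detected" when the curve rises at least
0.05 OD above its first read *and* its maximum comes within 0.05 OD of the
0.3 threshold. The rise condition alone would let reader drift on a flat
well count as growth; the threshold-approach condition prevents inverting
a regression fitted far below the threshold. Samples without detected
growth are right-censored: they are assigned 15 h — one hour past the
horizon — and enter all downstream statistics at that value (no
survival-model treatment; the censored value is an ordinary observation).

**Linear-range selection.** The linear phase is found by exhaustive
search over contiguous windows of ≥ 3 points: among windows with a
positive OLS slope whose OD span covers the crossing, the one with the
highest r² wins, ties going to the longer window and then the earlier
start. "Covers the crossing" means the window either brackets the
threshold (a point at or below 0.3 and one at or above) or contains the
first above-threshold read. The second clause matters for fast growers:
when the curve jumps the threshold inside the unobserved 0–5 h gap, the
only below-threshold point is the flat time-zero read, and forcing it
into the fit would bias the slope downward. r² comparisons use a 1e-9
tie tolerance. Crossing times extrapolated beyond the horizon but finite
are kept as computed; only no-growth samples receive the censor value.

**Classification.** Relative to the arithmetic-mean crossing time of the
plasma-free controls (four per run by design; other counts are accepted
with a warning): crossing at or before the control mean is *no killing*,
later is *intermediate killing*, censored is *absolute killing*. The
boundary is inclusive on the no-killing side. Technical replicates are
averaged on the hours scale before the log transform.

Identifiability: a crossing time earlier than the 5 h read cannot be
estimated from this schedule — there are no rise-phase points. This never
occurs in the emulated design, where plasma can only delay growth
relative to controls crossing at ~5.5 h; accuracy statements therefore
apply to curves whose crossing is at or after the first post-lag read.

## ELISA quantification

Replicate wells are aggregated as mean/SD/SE with no outlier removal;
replicate counts come from the plate layout (duplicate and triplicate
both occur in practice). Background testing follows the assay-validation
design: the maximal-staining sample, the minimal-staining sample and the
secondary-antibody-only wells are each compared to the BSA blanks with a
two-sided Mann–Whitney test at the Bonferroni level 0.05/3 ≈ 0.0167. The
"non-parametric t-test" of such designs is read as the rank-sum test —
the standard nonparametric two-group location test. With both groups of
size ≤ 8 the p-value is computed by exhaustive enumeration of all
C(n+m, n) group assignments of the pooled values (ties contribute one
half to U; an assignment counts as extreme when |U − nm/2| is at least
the observed deviation, within 1e-12); larger groups use the normal
approximation with tie and continuity corrections. Note the exact test's
granularity: with a duplicate sample against three blanks the smallest
attainable two-sided p is 0.2, so small-plate comparisons can be
non-significant at the corrected level no matter how separated the
values — an inherent property of exact rank tests at these sizes, not a
defect of the data.

Competition specificity is 1 − (competed mean)/(uncompeted mean); it is
scale-invariant and can be negative if competition increases signal. No
blank subtraction is applied to reported means (backgrounds are reported
alongside); blank-corrected values can be derived from the outputs.

The total-IgM standard curve is a four-parameter logistic fitted by
least squares to the kit standards (replicates averaged per
concentration, ≥ 4 distinct concentrations, monotone required), with a
linear-in-log10-concentration fallback if the optimiser fails.
Interpolation inverts the fitted curve; queries outside the standards'
fitted OD span are flagged out-of-range, never extrapolated.

## Population models

Both responses are analysed on the natural-log scale — the ELISA signal
as ln(mean A450), the killing score already as ln(hours) — with a linear
mixed model: population as the fixed effect and a random intercept per
sex, fitted by REML (statsmodels MixedLM; optimiser retries with Powell
and CG before declaring non-convergence, and a documented OLS fallback
treats the boundary case sd_sex → 0). Sex enters as a random effect
because field cohorts are not sex-balanced. The fixed-effect p-value is
a Wald z-test by default; a likelihood-ratio test (ML fits, χ²₁) is
available behind a flag. Modelling the log response with an identity
link was chosen over a log-link GLMM on the raw response: the two are
stated interchangeably in this assay literature, and the log-transformed
dependent variable is the explicit quantity here (censored values enter
as ln 15).

With only two random-effect levels the sex variance is weakly
identified; calibration was checked by simulation rather than assumed:
under the null (equal populations, sex sd 0.3, 40 animals per
population) the empirical type-I error at nominal 0.05 is ~0.05–0.07,
and the 95% Wald CI covers a true ln-scale shift of 1.0 in ~94% of
simulated studies (200 seeds each; recomputed by the test suite and
`scripts/acceptance.py`).

Cross-assay regressions are simple OLS with r², slope t-test and
pointwise 95% confidence band for the mean line.

## The synthetic cohort generator

The generator is the package's test bed: it produces growth curves,
ELISA plates, metadata and a truth record from one seeded RNG stream, so
identical configurations are byte-identical.

Per animal: latent ln-nAb = population mean + sex intercept
(N(0, 0.3²), one draw per sex) + individual noise (N(0, 0.5²)); the
ELISA signal is exp(latent) — lognormal, since ODs are positive and
right-skewed. Killing strength (hours of growth delay) is
7·(latent − (−0.75)) + N(0, 2.8²). Defaults (populations of 43 and 50,
latent means −0.8 and −0.2) were set analytically from normal-tail
algebra so that roughly half of the low-nAb population shows no killing,
about one animal in it suppresses growth completely, and about a fifth
of the high-nAb population reaches complete suppression — the class
structure of the field study being emulated. Suppression is emergent: a
delay pushing the growth lag past the 14 h horizon leaves nothing
detectable, with no separate "killed" assignment.

Growth curves are piecewise linear (flat lag at baseline OD 0.05 →
linear rise at 0.1 OD/h → plateau at 0.9), with N(0, 0.01²) read noise
truncated at zero; a logistic shape with matched midpoint and maximal
slope is available for robustness checks of the linear-phase estimator.
Plasma-free controls (four) use the base 3 h lag, crossing at 5.5 h.
Heat-inactivated aliquots — and plasma whose net killing strength is
negative — get a lag 0.3 h *shorter* than controls: diluted plasma acts
as a mild nutrient source once its heat-labile killing component is
gone. Besides being biologically defensible, the margin keeps
killing-free samples off the knife-edge of the inclusive "≤ control
mean" class boundary, where symmetric read noise would otherwise flip
half of them to intermediate killing.

ELISA wells scatter multiplicatively around the latent signal at 10% CV
(floor 0.001). Competition pairs (six) lose a Beta-distributed fraction
of signal with mean 0.93 and sd 0.12 — the Beta is the natural bounded
law with those moments, and any [0,1] law with them is strongly
left-skewed, so single six-pair studies scatter widely around 93% while
the across-study mean is pinned. Total IgM is built from the measured
nAb signal by orthogonalised residuals so the realized squared
correlation equals the 0.25 target exactly in every cohort (then mapped
to a 2.0 ± 0.5 mg/ml scale). Kit standards (eight 2-fold steps,
25–3200 ng/ml) follow a known 4PL with small read noise. Plates carry
three BSA and three secondary-only wells each; an optional per-plate
intercept defaults to zero since no batch structure is asserted.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: plate-edge and drift artefacts, pipetting
outliers, non-monotone or double-phase growth curves, true biological
coupling between total IgM and nAb beyond the imposed correlation, and —
importantly — killing variance unrelated to nAb. With the single
nAb→killing mechanism, a population separation strong enough to produce
the emulated killing-class structure necessarily couples the two assays
tightly at the individual level (cross-assay r² ≈ 0.5 in synthetic
cohorts), whereas real cohorts show much looser individual-level
coupling (r² an order of magnitude lower): real killing capacity must
carry substantial non-nAb variance (complement levels, IgG, antibody
glycosylation) with population structure of its own, which this
generator deliberately does not model.

## Problem sizes and numerics

Test-suite and acceptance-script simulations use 80–200 animals per
cohort and 100–200 seeds per calibration, sizes at which Monte-Carlo
error is well inside the tolerances checked. Window search is O(n²) in
the (eleven) reads per curve. Degenerate inputs fail loudly: flat
windows cannot be inverted, censored controls abort the baseline,
non-monotone standards abort the curve fit, duplicate wells, duplicate
time points and negative ODs are rejected at parse time with the
offending row named. CSV floats are read with round-trip precision so
writer/reader pairs are lossless.
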