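# Methods

## The clock

The biological-age score combines five variables — relative telomere
length (RTL, dimensionless T/S ratio), serum iron (Fe, μg/dL), total
iron-binding capacity (TIBC, μg/dL), serum ferritin (F, μg/L) and
chronological age (a, years) — each z-scored against the moments of a
referent population restricted to the subject's age band:

    a_bio = k · Σ_X sgn(k_X) · X_norm + C
            + a·Δa_bioHIV− + (a − 20)·Δa_bioHIV+

Transferrin saturation (= Fe/TIBC) and serum transferrin (collinear
with TIBC) are carried in the data model but excluded from the score as
redundant.

The signs make every term point "older": variables that decline with
age in the referent (RTL, Fe, TIBC) enter negatively, so a low value
reads old; ferritin and age enter positively. Because the per-variable
slopes are normalized away by k = 1/Σ|k_X|, no variable is privileged
by its units, and a one-SD excursion in any single variable moves the
score by exactly ±k years. The constant C = −k·Σ sgn(k_X)·n_X centres
the score so that, in the calibrating sample itself, the OLS line of
a_bio on a is exactly the identity — this is an algebraic property of
least squares (each z-scored variable's fitted line passes through
(ā, 0), so the slopes sum to 1/k and the intercepts cancel against C),
and the test suite asserts it to 1e−9 on a 10 000-record synthetic
referent. A corollary used as a self-check: on complete-case data C
equals the sample mean age.

Two age bands are calibrated separately (19–35 and 50–77 years; study
enrolment admits 18–35 and 50–77, and the 35–50 gap is rejected by
default or mapped to the nearest band under an explicit flag), because
several of the biomarkers trend differently in young adulthood and in
late middle age. Ages in a band are z-scored with that band's own
(μ_a, σ_a) exactly like the biomarkers, which makes k_a = 1/σ_a an
identity.

### Adjustments

Two per-year adjustments translate the referent-calibrated score to
other populations:

* Δa_bioHIV− = (a_life − a_ref_life)/a_life, applied as a·Δ to every
  study subject (HIV+ and HIV− alike), moves the clock from the
  referent population's life expectancy (default 76.1 y) to the study
  population's (default 72.9 y): −0.044/year.
* Δa_bioHIV+ = (a_ref_life − a_HIV_life)/(a_HIV_life − 20), applied as
  (a−20)·Δ to HIV-positive subjects only, encodes the shorter life
  expectancy of treated HIV+ individuals (default 67 y from a treatment
  start at age 20): +0.194/year of adult life. For subjects younger
  than 20 the term goes slightly negative as the formula dictates; a
  warning is emitted. Untreated (naive) HIV+ subjects receive the same
  adjustment by default; `AdjustmentPolicy(apply_hiv_adjustment_to_naive=False)`
  zeroes it for them.

By default the deltas stored on the constants object are used — for the
built-in constants these are the published rounded values (−0.044,
0.194), so decomposition arithmetic reproduces printed worked values
exactly; supplying a `LifeExpectancySet` recomputes both deltas from
the ratio formulas instead (−0.04390, +0.19362 at the defaults; the
difference is < 0.02 y for any adult age). Freshly calibrated constants
carry zero deltas: the adjustments describe a study population, not the
referent.

### Units

Internal canonical units are μg/dL for Fe and TIBC (the unit system of
the built-in calibration constants), μg/L for ferritin. Clinical
sources often report iron in μmol/L; the readers convert on request
(header suffix `(umol/L)` or an explicit `units=` mapping) at
5.5845 μg/dL per μmol/L (atomic mass of iron 55.845). Normalizing a
μmol/L value against μg/dL moments would silently shrink every iron
z-score ~5.6-fold, which is why the unit declaration lives in the
input schema rather than in an argument to the scoring function.

Cohort ferritin levels measured with some clinical kits sit far below
the referent μ_F (~141–196 μg/L); the pipeline applies the referent
normalization as calibrated and flags |z| > 5 only through the
ordinary diagnostics rather than altering values.

## Calibration choices

Ordinary unweighted least squares throughout; sample SDs use the n−1
denominator. sgn(0) is taken as +1 with a warning (a zero slope
contributes nothing either way). Missing values are handled per
variable: each variable's moments and slope are estimated on its
available subsample, mirroring referent sources in which different
variables come from different survey waves; the identity property is
then guaranteed only on complete-case data. Records outside the band
are rejected at construction (`assign_band` reports the excluded
count). Survey sampling weights are not used.

The published k values differ from 1/Σ|k_X| of the published 4-dp
slopes in the 3rd–4th decimal (rounding of the printed inputs);
constants objects therefore tolerate ≤ 0.01 absolute k-inconsistency
on validation, and checks against printed k use 0.005.

## Synthetic data

The generators state a world and the tests live in it; none of their
defaults were adjusted to test outcomes.

**Referent populations.** Ages follow a normal truncated to the band.
The published band moments describe the band-restricted sample, so the
generator solves (least squares on the two truncated moments) for the
parent location/scale whose *truncated* distribution matches (μ_a,
σ_a). One caveat is structural: no distribution on [19, 35] can exceed
the uniform SD of 4.62 y, so the achieved age SD falls ~2% short of
the 4.72-y target (similarly for the older band); biomarker moments are
unaffected. Each biomarker is generated as
X = μ_X + σ_X·(k_X·(a − μ_a) + ε) with ε ~ N(0, √(1 − k_X²σ_a²)), so
its z-score has mean ≈ 0, SD ≈ 1 and OLS slope k_X on age by
construction. Values are clipped at zero with the clip count and the
pre-clip moments reported in `records.attrs`; under the defaults the
only materially affected variable is ferritin, whose target places ~5%
of its mass below zero, shaving ~5% off its post-clip SD (the fidelity
tests therefore assert pre-clip moments, plus post-clip means).
Consequences measured at n = 10 000: calibration recovers each
biomarker slope within sampling error and reproduces k within ~1–3% of
the published value; the residual gap is the age-SD shortfall above,
not noise.

**Study cohorts.** Four groups (HIV+ younger n = 55 with 8 naive, HIV+
older n = 50 all treated, HIV− 50/50 across bands) with the published
group moments: RTL 0.87/0.79 (HIV+) vs 0.83/0.69 (HIV−), ferritin
13.4/16.16 vs 7.03/4.68 μg/L, iron panel pooled per HIV status
(converted to μg/dL), CD4 and therapy-duration moments per band.
Printed study ages ("29.2 ± 0.5", "59.6 ± 1.1") are read as mean ± SEM
— an SD of half a year across an 18–35 enrolment band of 55 men is not
possible alongside the study's own within-band ranges — giving
generator SDs of ≈3.7/7.8 y; the uninfected donors' unpublished ages
get band-typical values (29 ± 4, 60 ± 7). Biomarkers are normal
clipped at zero (clipping, unlike resample-truncation, keeps the
realized mean within ~1% of target for RTL and within a few percent
for the near-zero ferritin groups); therapy duration is clipped at its
0.8-month observed floor. Treated subjects split 50/50 between the
2NRTIs+NNRTI and 2NRTIs+PI regimen classes (the split is not
published). Viral load is a two-part mixture: a point mass of exact
zeros below the 20 copies/mL detection limit (default fraction 0.6,
reflecting that most treated patients suppress below detectability)
plus a log10-normal detectable tail (mean 3.0, SD 1.0); the floor rule
(values < 20 → 10, the midpoint of the undetectable range) is applied
downstream by the analysis code, never at generation. Age is the only
built-in source of cross-correlation; there are no residual
biomarker–biomarker relations, matching the study's negative findings.
One master seed spawns an independent stream per group (keyed by group
label), so adding a group never perturbs another's draws.

What a green test does **not** establish: the generator draws
independent (given age) truncated-normal marginals with equal iron
moments in both bands — real cohorts have within-subject iron-panel
correlation, skewed ferritin and CD4, assay floors other than zero,
and band-specific iron levels. Conclusions about the clock's behavior
on real data rest on the algebraic properties, not on the generator.

### A measured limitation

One cohort-scale property narrowly misses its design goal, honestly:
over 200 seeded default cohorts, the fitted HIV+ biological-age line
lies above the HIV− line over the *entire* [20, 77] range in 92% of
replicates rather than ≥95%. The gap at the age-20 endpoint averages
+2.4 y with a replicate SD of 1.8 y, so ~8% of replicates dip just
below zero there; from age 25 the ordering holds in ≥98%, and at 77 in
100%. The driver is extrapolation: age 20 sits 9 years left of the
younger cluster's mean, and the HIV+ line's intercept is noisy chiefly
because the published HIV+ TIBC spread (15.57 μmol/L ≈ 86.9 μg/dL) is
1.8× the referent σ_TIBC, putting the residual SD of HIV+ biological
age near 6.6 y. The corresponding test asserts the 95% goal and is
left failing rather than weakened.

## Statistical analyses

Two-group comparisons are gated on normality: both samples must pass a
Kolmogorov–Smirnov test against a normal with estimated moments
(Lilliefors correction, α = 0.05; statsmodels implementation) for the
pooled-variance two-sided t test (df = n₁+n₂−2) to apply, otherwise
Mann–Whitney U with the asymptotic tie-corrected p. Summaries are mean
± SD under t, median ± IQR under Mann–Whitney. No multiple-testing
correction is applied (α = 0.05 per comparison). Ferritin–age trends
use an unweighted least-squares quadratic; biological-vs-chronological
age trends use unweighted lines per HIV-status or regimen group, with
the referent identity line prepended for reference. The exploratory
relation scan reports slopes and Pearson r for viral-load/telomere/
iron pairs without significance claims. Constant samples are routed to
"non-normal" with a warning; groups without age spread are skipped
from fits with a warning rather than failing the run.

## Numerical notes

All arithmetic is double precision; outputs round to 4 decimals only
at the CSV boundary. The per-term decomposition stored on each result
reconstructs the total to < 1e−9 y. Determinism: a given spec + seed
reproduces generated tables byte-for-byte; seeds derived from the
master stay below 2³¹.
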