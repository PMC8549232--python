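# Methods

## Coordinate model and file formats

All analysis happens in *target-layout coordinates*: millimetres, origin at
the centre of the proximal target, +y toward the distal target (default
(0, 300)), +x to the subject's right. A recording's registration — which
sensor cell the origin sits on and which grid axis carries y — is part of
`MatGeometry` (`origin_cell`, `y_axis`) and of every file header, because a
mat can be laid out in any orientation relative to the chair. A sensor
cell's coordinate is its centre; indices are 0-based `(row, col)`.

Two open text dialects are defined (`frame_text`: dense per-frame grids
with a key=value header; `long_csv`: sparse `t,row,col,force` rows plus a
YAML sidecar). Vendor binary exports are deliberately out of scope; they
are undocumented, and any dense or sparse grid export can be converted to
these dialects losslessly. Forces are written at full precision, so
save→load is the identity on forces and timestamps round-trip far below
1 µs. Recordings must have strictly increasing timestamps with inter-frame
spacing within 10% of the nominal 1/rate; time-of-touch needs only frame
ordering, so larger jitter indicates a corrupt file and is rejected rather
than resampled.

## Touch detection

A cell is *active* when its force reaches `force_threshold` (default 1
device unit). A frame participates in an episode when its total
above-threshold force reaches `min_total_force` (default 3); a **contact
episode** is a maximal run of at least `min_duration` (default 2)
consecutive such frames, separated by at least one inactive frame. The
per-frame analysed region is the largest 8-connected component of active
cells; ties go to the component with greater total force, then to the one
nearest row 0. The protocol puts one foot on the mat, so any secondary
disjoint contact is dropped (and logged at debug level).

The **endpoint** rule extracts the big toe from the force distribution:
take the *extremal cell* — the active cell whose centre is nearest the
intended target's centre — and form the force-weighted centroid of the
active cells within `toe_radius_mm` (default 20 mm, about the width of a
big toe, 2–3 cells) of it. For a toe-sized contact this equals the region
COP; for a whole-foot landing it isolates the target-most (toe) end. The
**time of touch** is the earliest frame of the episode whose endpoint is
closest to the intended target's centre, ties resolved to the earlier
frame. **COP** and **surface** are computed over the whole contact region
at the time of touch — the contact surface is what presses on the ground,
not just the toe — while the endpoint is toe-only; this split is the
natural reading of the measurement goals, and computing both from the same
region structure means the alternative (toe-only COP) is a one-line change.

The intended target follows the alternation protocol: an episode whose
final-frame contact lies in a target zone is assigned that zone's target;
an episode that never reaches a zone (a drag) is assigned the opposite of
the previous in/out touch's target, proximal at the start of a trial. Each
episode yields exactly one touch event; a slide crossing zones is judged at
its time of touch. Identical recording + configuration always produce the
identical event list.

Known limitation: for a whole-foot landing that substantially overshoots
the proximal target, arch cells can lie closer to the target centre than
the toe, and the extremal-cell rule then anchors on the arch. This is an
intrinsic ambiguity of "the contact point nearest the target" when the
foot crosses the target; the localisation guarantees below are therefore
stated for toe-dominant contacts.

## Scoring

Zones are judged on y only: closed bands of ±`zone_half_width_mm`
(default 100 mm) around each target centre; the bands cannot overlap (300 mm
separation vs 200 mm of band). In/out uses the closed disc of
`target_radius_mm`. The physical target diameter is not standardised for
painted targets, so the radius is an explicit configuration (default 25 mm)
echoed in every output header — never a silent constant. Closed boundaries
give deterministic behaviour that favours the participant.

Per-touch parameters are computed for in and out touches (between-target
drags are counted but carry no parameters); a `params_scope` switch
restricts to in-only. Variable error groups touches by target within the
trial's leg, as "the mean position of the same leg and target" requires;
a `variable_error_pooling="pooled"` option instead centres each touch on
its own target and pools both targets, for the alternative reading of how
per-leg consistency should be aggregated. A group with fewer than two
touches has undefined (NaN) variable error — a participant who touches a
target once is a real case and must not crash or impute.

## Statistics

*Count validation.* `manual ~ script` with a random subject intercept
(statsmodels MixedLM, REML), because each subject contributes two legs.
Conditional pseudo-R² follows the variance-partition form: (var of fixed
predictions + random-intercept variance) / (those + residual variance).
Perfect agreement has zero residual variance, where a mixed fit is
singular; the code detects singular/non-finite fits and falls back to OLS
with a logged warning, which yields the exact fixed point (slope 1,
intercept 0, R² 1). Agreement is summarised by the median manual−script
difference and the empirical 2.5/97.5 percentiles, plus the OLS slope of
the difference on the manual count (does the examiner's error grow with
how much they must count?).

*Speed–accuracy control.* Error parameters rise with touch rate, so a
group comparison must not reward slowness. A straight line of
Ln(parameter) on the raw in-target count — the simplest form consistent
with a positive speed–accuracy relation — is fitted on control rows only;
every row's residual (observed − predicted) is the speed-controlled value.
An Ln–Ln form is available behind `form="ln_ln"`. Logs are natural logs of
strictly positive values; a non-positive value names its row and raises —
no silent offsets.

*Group × leg models.* Legs are paired across groups into a two-level
within-subject factor (`leg_a` = paretic/dominant, `leg_b` =
non-paretic/non-dominant, the first-/second-tested pairing). With two legs
per subject, the random-intercept mixed model is the classical split-plot
design, and the F tests are computed in that form (pingouin
`mixed_anova`): group against the between-subject stratum, leg and
group × leg against the within-subject stratum. Under balance these tests
are exact, which the calibration test verifies empirically (type-I error
within binomial bounds of 5% over 1000 null replicates). Subjects missing
a leg or an outcome are dropped with a warning. Marginal means are cell
means ± SEM. The six pairwise cell comparisons use paired t within group,
Welch t across groups, adjusted by Holm's step-down (sequential
Bonferroni); the df method and adjustment are recorded in the result
metadata, and exact replication of any particular software's denominator
df is a non-goal. A constant outcome returns the all-zero F table rather
than crashing.

*Associations.* Spearman's ρ with effect-size labels at |ρ| ≥ 0.10 / 0.30 /
0.50 (small/medium/large); constant input yields a flagged undefined
result.

## Simulator

The simulator is the package's source of ground truth. A trial is a
schedule of alternating reaches at `touch_rate_hz`; each touch renders one
approach-ramp frame (half force, displaced 16 mm radially away from the
target, so the time-of-touch rule has something to reject) followed by
full-contact frames (150 ms dwell, 9 frames at 60 Hz). Contacts are
isotropic 2-D Gaussian force blobs sampled at cell centres and truncated
at the activation threshold:

- the **toe** blob at the true endpoint (target + bias + isotropic scatter
  of sd `endpoint_scatter_sd_mm`);
- a **forefoot pad** blob of equal mass placed laterally away from the
  target at twice the drawn COP offset, so the combined centroid sits the
  configured distance from the toe. The lateral-outward placement is
  deliberate: it guarantees the pad never contributes cells closer to the
  target than the toe, keeping the endpoint estimator unbiased, at the
  price of a stylised offset direction;
- optionally a **heel** blob (double sd, 0.6× peak) 100 mm toward the
  subject plus a connecting arch ridge, emulating a whole-foot landing
  (larger surface, large endpoint–COP separation);
- with probability `p_between` per reach, a short 3-frame **drag** contact
  in the between-target zone;
- i.i.d. per-cell sensor noise, clipped below the activation threshold so
  it perturbs forces without ever creating phantom contacts.

Truth per touch: the continuous endpoint, the force centroid of the
noiseless rendered contact (the reference for COP recovery), the rendered
cell count, and zone/hit labels from the layout applied to the true
endpoint. `boundary_guard_mm` resamples endpoints landing within a margin
of the disc or zone-band boundaries; label-exactness experiments use a
12 mm guard because detection on an 8 mm grid localises the endpoint to
about one cell (up to ~6 mm radially) plus a few mm of pad pull, and truth
labels within that distance of a boundary are not decidable from the grid.
The guard is off by default.

Default conditions mirror a stroke-vs-control study: controls at
~1.8 touches/s with 10 mm scatter and toe-sized contacts; the paretic leg
at ~0.8 touches/s with 13 mm scatter, larger COP offset, whole-foot
(heel) contact and a 25% drag rate; the non-paretic leg in between. These
rates reproduce in-target counts around 33–35 (controls) and 13–17
(stroke), with out and between counts of the observed order.

`simulate_cohort` emits one observation row per subject-leg. The rendered
path pushes every trial through the real detection pipeline. The default
analytic path draws parameters directly as log-normals around
condition-implied means (Rayleigh mean σ√(π/2) for scatter-driven errors,
truncation-radius area for surface) with a subject random intercept
(sd 0.2 on the log scale) and residual (sd 0.2) — exactly the generative
form the mixed models assume, which is what makes the calibration test a
test of the test rather than of the generator. The analytic means are
closed-form approximations; only their ordering and rough magnitude
matter downstream. Manual counts add a binomial per-touch overcount
(default rate 0.05), reproducing the examiner bias pattern in which the
count difference grows with the count.

## Problem sizes and numerical choices

Tests and the acceptance script use 8–20 s trials, cohorts of 4–40
subjects per group, 400–1000 replicates for calibration and 5–20 for
power-style checks — sizes chosen so the whole suite runs on a laptop in a
few minutes while keeping Monte-Carlo error well inside the asserted
bounds. Formula-level checks run against brute-force oracles at 1e-9
relative tolerance. All randomness flows through seeded
`numpy.random.default_rng` generators; every result artifact records its
seed.

## What passing tests do and do not show

The simulator produces everything the analysis measures — but as idealised
Gaussian contacts. Real plantar pressure has anatomy (five toes, a
non-elliptical forefoot, rollover dynamics), device-specific calibration
and hysteresis, and occasionally two feet or a cane on the mat. Passing
tests therefore demonstrate that the algorithms are correct on
well-defined contacts and that the statistical layer is calibrated; they
do not certify endpoint accuracy on arbitrary real feet, and the detection
thresholds will need per-device tuning (they are all configuration, not
constants).
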