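# Methods

This note documents the models, conventions and numerical choices behind
`ssgpos`, including the points where the design was genuinely open and what
the synthetic-data tests do and do not establish about real tracking data.

## Coordinate chain

GPS fixes (WGS84 lat/lon) are projected with a transverse Mercator
implementation using the Krüger series in the third flattening, 6th order —
accurate to well under a millimeter inside a UTM zone's 3° half-width
(verified in the tests against an independent USGS/Snyder-series
formulation and against Karney-geodesic ground distances).  All players of
a session are forced into one zone, chosen from the mean longitude: a 42 m
pitch never spans zones, and mixing zones would corrupt distances.  The
WGS84 ellipsoid is assumed.

The field frame is calibrated from the four pitch vertices.  Vertices may
arrive in any order; they must form an approximate rectangle (opposite-side
mismatch < 5 %, the tolerance that separates GPS survey noise from a wrong
corner).  The longer side pair defines the length axis.  Two corners could
serve as origin; the one with the smaller (y, x) projected coordinate is
chosen, deterministically, so exported coordinates are reproducible.  The
resulting map is a proper isometry (rotation + translation, det = +1):
pairwise distances are preserved exactly, and positions slightly outside
the pitch are kept rather than clipped, since clipping would bias the
extent metrics.

Note that planar UTM distances carry the grid scale factor (0.9996 at the
central meridian, unity about 180 km out).  Over a pitch this is millimeters
to a centimeter and far below GPS noise; no scale correction is applied.

## Regularization and smoothing

All players are resampled onto one uniform grid (default 10 Hz) spanning
the bout.  Gaps up to `max_gap_s` (default 0.5 s, i.e. 5 samples) are
linearly interpolated; longer gaps leave NaN frames and split the series
into segments, reported per player.  Interpolation never extrapolates.  A
player covering less than half the bout is rejected rather than silently
averaged in.

Smoothing is a second-order Butterworth low-pass at 0.5 Hz.  Whether the
original processing was causal or zero-phase is not documented anywhere we
could find; zero-phase (forward–backward) is the default because a causal
second-order filter at these settings lags positions by roughly 0.3 s,
which would systematically distort frame-by-frame dyad coordination.  A
causal mode is retained for sensitivity checks.  The digital design uses
the bilinear transform with cutoff prewarping, so the exact magnitude
response is `1/sqrt(1 + (tan(πf/fs)/tan(πfc/fs))^4)` per pass, squared in
zero-phase mode; the −3 dB point sits exactly at the cutoff.  Segments are
filtered independently with reflective padding of about three filter time
constants; segments shorter than ~3 filter orders are left unfiltered and
flagged.

The pipeline order is project → regularize → filter → rotate.  Because the
rotation is an isometry applied per frame, filtering before or after
rotating gives identical results; the order is a presentation choice, not a
scientific one.

## Metrics

Length and width are the extreme-player extents along the pitch axes, not
convex-hull measures.  The stretch index is implemented as the mean radial
distance of outfield players from their team centroid — the established
definition in the positional-analysis literature; the term is used loosely
in parts of the applied literature, so the definition is pinned here.  The
LpW ratio is undefined on zero-width frames; such frames are excluded from
bout means and counted, never clamped, because clamping fabricates values.
The SEI distance is Euclidean in the plane.  Goalkeepers are excluded from
all collective and coordination computations unless explicitly requested;
results with the flag off are identical to computing on the outfield-only
subset.

Bout means are taken over all frames: ball-possession phases were not
tracked, so no ball-in-play filtering is possible.

## Vector coding

The coupling angle of a dyad on one axis is the angle of the paired
displacement vector (player A horizontal, player B vertical), mapped to
[0°, 360°).  Band boundaries are lower-inclusive / upper-exclusive; a fine
sweep test pins the convention by checking that exactly 90° of angle
measure falls in each diagonal class.  Frames where **both** displacements
are below ε = 0.01 m are excluded — the direction of a sub-centimeter
frame-to-frame step is GPS noise, not movement — while frames where only
one player is quasi-static are kept (genuine axis cases).  ε is
configurable and the excluded share is always reported.  Angles are pooled
within a bout; the bout is the statistical unit.  The team-level value is
the unweighted mean over the six dyads (the pooled-frames alternative is
available by aggregating the per-dyad counts, but mean-of-dyads is the
default because it weights each pair equally regardless of exclusions).
No angular smoothing is applied on top of the trajectory smoothing.

## Synthetic generator

The generator emulates the study conditions: two teams of four outfield
players (plus optional goalkeepers) on a 42 × 29 m pitch, 10 Hz, 4-minute
bouts.  Each player's position is

    p_j(t) = anchor_j + κ · g_team(t) · ê_x + e_j(t),

where `g_team` is a team-shared longitudinal drive (sum of 6 random-phase
sinusoids in 0.04–0.20 Hz, unit RMS — entirely below the 0.5 Hz analysis
cutoff, so preprocessing cannot destroy the planted coupling) and `e_j` is
an independent per-player mean-reverting excursion: an exact AR(1)
discretization of an Ornstein–Uhlenbeck process (θ = 0.15 s⁻¹), band-limited
below the analysis cutoff like real smoothed trajectories and renormalized
analytically to a stationary standard deviation of `exploration_sd` meters.
Positions are folded back into the pitch extended by a 2 m margin.

The three dials map one-to-one onto the measured phenomena, and the tests
verify the mapping is monotone (Spearman ρ > 0.9 over 5 levels × 10 seeds):

- `coupling_gain` κ (meters): amplitude of the shared drive → longitudinal
  in-phase percentage;
- `exploration_sd` σ (meters): excursion scale → SEI;
- `spread_gain`: anchor dispersion → team length and width.

Anchors default to a diamond per team (±6 m offsets from the team center,
mirrored between teams); goalkeepers get near-goal anchors, κ = 0 and 15 %
of the outfield σ, exercising the exclusion path.

Condition presets emulate the four experimental protocols' *orderings*
(free play FR; explicit high-press rule R1; implicit rule R2; both rules
R3): R1 plants the strongest drive (κ = 3.6) and widest exploration
(σ = 6.3) plus a 15 % larger spread; R2 a strong drive (κ = 2.8) with
near-baseline exploration; R3 sits close to FR (κ = 2.2 vs 2.0).  σ values
(5.6–6.3 m) were chosen so simulated SEI lands in the 7–8.5 m range typical
of 4-a-side games on this pitch, with the SEI ordering
R1 > R3 > R2 > FR and the in-phase ordering R1 > R2 > R3 ≈ FR.

What the generator does **not** model: a ball, opponent interaction,
tactical rules, game phases, fatigue, or GPS error structure
(multipath, fix dropout correlations).  Passing tests therefore establish
that the pipeline recovers known planted structure of this kind, not that
the pipeline is unbiased for every feature of real tracking data.

## Statistics

All test statistics are computed from first principles; scipy supplies only
distribution functions, and the test suite cross-checks every procedure
against an independent implementation (scipy, pingouin, statsmodels).

- **Normality gate.**  Shapiro-Wilk per condition at α = 0.05; a variable
  is routed nonparametric if any condition rejects.  Constant samples are
  flagged nonparametric with a warning.
- **Friedman.**  Mid-ranks within units, standard tie correction in the
  denominator.  Dunn's post hoc compares mean ranks with the normal
  approximation, Bonferroni-multiplied by k(k−1)/2 and capped at 1.
- **rm-ANOVA.**  One-way repeated measures; F = MS_cond / MS_(cond×unit);
  partial η² = SS_cond / (SS_cond + SS_error).  No sphericity correction by
  default (matching the analysis plan this mirrors); the Greenhouse–Geisser
  epsilon is reported alongside so a corrected p can be formed.
- **MANOVA.**  One-way on condition; Pillai's trace V = tr(H(H+E)⁻¹) with
  the standard F approximation; the multivariate partial η² is V/s,
  s = min(p, k−1).
- **Effect taxonomy.**  no < 0.04 ≤ minimum < 0.25 ≤ moderate < 0.64 ≤
  strong, boundaries lower-inclusive.  (Applied papers occasionally label
  η²p values near 0.1 "moderate"; this implementation follows the printed
  thresholds, under which such values are "minimum".)
- **ICC(3,1).**  Two-way mixed, consistency, single measure, with the
  F-based confidence interval.

Units of analysis follow the mixed convention of the field: team-bout for
collective variables, player for SEI, dyad-mean (team level) for
coordination; all are configurable through how the condition dataset is
pivoted.

Calibration: under null synthetic datasets (identical condition parameters,
8 units × 4 conditions, 1000 replicates at 20 s bout length — the bout
length only scales the summary variance, not the tests' validity), the
rejection rates of both Friedman and rm-ANOVA at α = 0.05 stay within
[0.03, 0.07], and power rises monotonically with planted effect size.
Simulation sizes throughout the suite (20–240 s bouts, 4–8 sessions) were
chosen as the smallest that leave the checked orderings clearly resolved.

## Known limitations

- The sample-size arithmetic of the original study design (a power analysis
  requiring an unreported repeated-measures correlation) is out of scope.
- Video-based tactical rating (the observational instrument whose
  reliability ICC(3,1) quantifies) is human work; only the agreement
  statistics are implemented.
- Segment splitting on long gaps is conservative: metrics are computed on
  observed frames only, and no imputation beyond 0.5 s is attempted.
- The Dunn post hoc uses the large-sample normal approximation; at very
  small unit counts its p-values are approximate (the omnibus Friedman
  p is exact-in-distribution only asymptotically as well).
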