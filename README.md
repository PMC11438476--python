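# ssgpos

Positional and interpersonal-coordination analysis of small-sided soccer
games (SSGs) from 10 Hz GPS tracking.

Sports scientists use SSGs — here 4 vs 4 plus goalkeepers on a 42 × 29 m
pitch — to study how task constraints shape tactical behavior.  The raw
material is a per-player stream of WGS84 latitude/longitude fixes; the
quantities of interest are collective spatial-occupation metrics, an
individual exploration index, and dyadic movement coordination, compared
across repeated experimental conditions.  `ssgpos` implements that full
chain as a tested, reusable library plus a thin CLI, together with a
synthetic two-team generator so every stage can be validated against known
ground truth.

## What it computes

**Preprocessing.**  Raw fixes are projected to planar meters (UTM, Krüger
series on WGS84), re-gridded to a common uniform 10 Hz time base (short
dropouts interpolated, long ones split into segments), smoothed with a
second-order 0.5 Hz Butterworth low-pass (zero-phase by default), and
rotated into a pitch-aligned frame calibrated from the four field vertices
(x along the pitch length, y along the width).

**Collective metrics (per frame, per team, outfield players).**

- length `L = max(x) − min(x)` and width `W = max(y) − min(y)`;
- LpW ratio `L / W` (team's preferred positional axis; undefined frames
  excluded, not clamped);
- centroid (mean position) and the inter-team centroid distance;
- stretch index: mean player distance from the centroid.

**Spatial exploration index (per player).**
`SEI = mean_t ‖p(t) − p̄‖`, the average distance between a player's
instantaneous and bout-mean positions.

**Interpersonal coordination (vector coding).**  For each same-team dyad
and axis, the coupling angle per frame is
`γ(t) = atan2(Δx_B, Δx_A) mod 360°`.  Angles in
[22.5°, 67.5°) ∪ [202.5°, 247.5°) are in-phase (co-directed motion), angles
in [112.5°, 157.5°) ∪ [292.5°, 337.5°) anti-phase (opposed motion).  Frames
where both displacements fall below a 0.01 m motion threshold are excluded.
A team's value is the unweighted mean over its six dyads.

**Statistics.**  A Shapiro-Wilk gate routes each bout-level variable to a
one-way repeated-measures ANOVA (Bonferroni post hoc) or to Friedman's test
(Dunn post hoc); several responses can enter a one-way MANOVA summarized by
Pillai's trace.  Effect sizes are partial η², labelled no / minimum /
moderate / strong at 0.04 / 0.25 / 0.64.  Observer agreement uses
ICC(3,1), the two-way mixed consistency single-measure intraclass
correlation.

## Worked example

```python
import numpy as np
import ssgpos as sp
from ssgpos.synthetic import SimulationParams, simulate_bout

traj, truth = simulate_bout(
    SimulationParams(coupling_gain=3.6, exploration_sd=6.3, seed=7)
)
team_a = sp.collective_frame_metrics(traj, "A")
print(f"team A mean length  : {np.nanmean(team_a.length_m):.2f} m")
print(f"team A mean width   : {np.nanmean(team_a.width_m):.2f} m")
print(f"team A stretch index: {np.nanmean(team_a.stretch_index_m):.2f} m")
print(f"mean SEI            : {np.mean([r.sei_m for r in sp.sei(traj)]):.2f} m")
dyads, team_mean = sp.team_dyad_summary(traj, "A", "longitudinal")
print(f"longitudinal in-phase : {team_mean['pct_in_phase']:.1f} %")
```

prints

```
team A mean length  : 14.84 m
team A mean width   : 16.29 m
team A stretch index: 8.19 m
mean SEI            : 7.86 m
longitudinal in-phase : 43.1 %
```

The simulated team occupies roughly a third of the pitch length, each
player roams about 8 m around their mean position, and the planted shared
longitudinal drive (`coupling_gain=3.6`) lifts in-phase coordination well
above the 25 % that an uncoordinated team would show by chance.

A four-condition repeated-measures fixture and its analysis:

```python
from ssgpos.synthetic import condition_presets, make_condition_dataset
from ssgpos import analyze_condition_dataset

ds = make_condition_dataset(condition_presets(), n_sessions=4, base_seed=1)
results = analyze_condition_dataset(ds, ["sei_mean_m", "in_phase_long_pct"])
```

The CLI runs the same pipeline from a JSON config:

```sh
ssgpos all --config config.json --seed 7 --out results/
```

## Layout

- `src/ssgpos/ingest.py` — CSV reading, UTM projection, field-frame calibration
- `src/ssgpos/preprocess.py` — regridding, gap handling, Butterworth smoothing
- `src/ssgpos/metrics.py` — collective metrics, SEI, bout summaries
- `src/ssgpos/coordination.py` — vector coding, phase classification
- `src/ssgpos/synthetic.py` — two-team generator with known ground truth
- `src/ssgpos/stats.py` — normality gate, rm-ANOVA, Friedman/Dunn, MANOVA, ICC(3,1)
- `src/ssgpos/cli.py` — config-driven pipeline
- `docs/methods.md` — models, parameters, design decisions, limitations
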