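# limbkine

Quantification of the two repetitive lower-limb items of the MDS-UPDRS
motor examination — toe tapping (item 3.7) and leg agility (item 3.8) —
from wearable IMU recordings, for movement-disorder researchers building
digital motor biomarkers.

Clinical rating of these items is a subjective 0–4 judgement. `limbkine`
replaces it with kinematics measured from two 100-Hz inertial sensors per
leg: the sagittal-plane foot angle (pitch) from a foot-mounted sensor for
toe tapping, and vertical acceleration from an ankle-mounted sensor for leg
agility. The package covers the full chain:

1. **Segmentation** — movement cycles are delimited by ground contacts:
   pitch local maxima above `TH_TT = −3°` with an intervening toes-up dip
   below `TH_TTup = −5°` (TT), or vertical-acceleration impact peaks above
   `TH_LA = 20 m/s²` (LA). Raw signals, no filtering.
2. **Per-cycle parameters** — frequency `f = 1/T`; peak-to-peak angle `A`;
   movement smoothness as dimensionless jerk
   `DLJ = (T⁵/A²)·∫(d³θ/dt³)² dt` and `LDLJ = ln DLJ`
   (a raised-cosine cycle gives exactly `(2π)⁶/8 ≈ 7691`);
   per-cycle maximum vertical acceleration; and the integral of the free
   acceleration-vector magnitude (IAV).
3. **Cohort statistics** — per-trial medians over the first 10 s pooled
   into median / IQR / %IQR reference rows by leg dominance, with exact
   paired Wilcoxon signed-rank tests of dominance differences.
4. **Interval models** — amplitude decrement across four 5-s intervals via
   the REML mixed model `angle ~ time, (time + dominance | participant)`
   (healthy reference: intercept ≈ 17.41°, slope ≈ −0.83°/interval; the
   frequency analogue stays near-constant at ≈ 2.75 Hz), plus the
   frequency–angle OLS with banded R², Levene and VIF diagnostics.
5. **Synthetic cohorts** — the study data are not redistributable, so a
   generator reproduces the healthy cohort's statistical structure
   (23 participants × 5 trials × 2 legs × 2 tasks, 20-s trials) with exact
   ground-truth event tables for oracle testing.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import limbkine as lk

# simulate the default 460-trial cohort and run the full analysis
analysis, sim = lk.simulate_and_analyze(cohort=lk.CohortGenParams(seed=0))
print(analysis.summary.query("task == 'TT' and parameter == 'angle'")
      .round(1).to_string(index=False))

fit = lk.fit_lmm(analysis.interval_medians, response="angle")
print(fit.summary())
```

prints (abridged):

```
task parameter    dominance  n_trials  median  iqr  pct_iqr pct_iqr_class
  TT     angle non_dominant       115    15.2  3.9     25.6         small
  TT     angle     dominant       115    15.4  3.8     24.5         small

Linear mixed model (REML): angle ~ time, random (Group + time + dominance | participant)
  rung: full   converged: True   singular: False
  n_obs = 911, n_participants = 23
  fixed effects:
    Intercept       17.5640  (SE 0.5183)
    time            -0.8035  (SE 0.0667)
  residual SD: 0.2522
```

Reading this: across 115 trials per leg the median tapping excursion is
≈ 15–16° with a small relative dispersion (%IQR < 30%), and the mixed model
recovers the generative decrement — tapping starts near 17.5° and loses
≈ 0.8° per 5-s interval, while participants vary around that fixed line
(random-intercept SD ≈ √6.19 ≈ 2.5°).

The same stages are scriptable from the shell:

```bash
limbkine run --seed 0 --out runs/demo          # full pipeline, all artifacts
limbkine simulate --task both --out sim --seed 3
limbkine segment --in sim/manifest.csv --out cycles.csv
limbkine extract --manifest sim/manifest.csv --window 0:10 --out features.csv
limbkine cohort --features features.csv --out table1.csv
```

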