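# otolunar

Reconstruction of lunar birth quarter from otolith daily-increment growth
histories, with a synthetic-cohort simulator and stage-transition selection
analysis.

Many reef fish spawn on a lunar schedule, and moonlight leaves a periodic
signature in the daily growth increments of larval otoliths. This package
implements the full inference chain around that signal:

1. **`otolunar.lunar`** — idealized lunar-phase arithmetic: phase angles,
   binning to the nearest quarter (new / waxing / full / waning), signed
   days from the nearest new moon, and the phase angle of a fish at a given
   larval age. A table of observed new-moon dates can replace the
   constant-rate clock for real-data work.
2. **`otolunar.simulate`** — a cohort simulator with known ground truth:
   new-moon-concentrated spawning, truncated-normal pelagic larval duration
   (PLD, mean 46 d on [37, 61]) with settlement attracted to the nearest
   *feasible* new moon, lunar-modulated daily growth, quarter-dependent
   survival through egg → settler → juvenile → adult, settlement-environment
   outcomes (offshore sites, group settlement), and a logistic primary-male
   determination rule on (largest-in-group, grouped, offshore).
3. **`otolunar.residuals`** — age-as-factor detrending (per-age mean radii),
   residual size-at-age, first-difference residual growth, per-fish
   z-scoring, 3-day centered rolling smoothing. A pluggable settlement
   correction hook (identity by default) can adjust increments spanning the
   settlement check.
4. **`otolunar.traits`** — the 12 growth-history features per fish: trend /
   linearity / curvature of the smoothed series (loess trend, orthogonal
   quadratic regression); OLS slope and intercept on the 28–34, 35–41 and
   42–48 dph windows; amplitude and offset of a lunar-periodic sinusoid
   fitted to raw residual growth at 25–47 dph (the phase parameter is
   estimated but deliberately not a trait); and PLD.
5. **`otolunar.classify`** — Gaussian equal-covariance linear discriminant
   over the 12 traits with per-fold standardization, leave-one-out
   cross-validation, equal ("uninformative") or training priors, confusion
   and adjacent-quarter misclassification accounting, and cohort assignment.
6. **`otolunar.selection`** — birth-quarter distributions per life stage and
   log10 proportion-ratio selection indices over the stage graph
   egg → settler → juvenile → {female, primary male} → terminal-phase male
   (14 transitions including composites), plus per-quarter settlement
   environment summaries.

## Command-line pipeline

```bash
otolunar simulate  --seed 1 --out cohort/            # increments.csv + truth.csv
otolunar residuals --in cohort/increments.csv --out residuals.csv
otolunar traits    --in cohort/increments.csv --out traits.csv
otolunar classify  --train traits_labelled.csv --apply traits_adults.csv \
                   --prior equal --out predictions.csv --confusion confusion.csv
otolunar select    --stages stages.csv --egg-dist egg.csv --out selection.csv
otolunar report    --cohort cohort/ --out report/    # summary tables + plots
```

`simulate --config params.yaml` accepts any `SimParams` field as a YAML key
(per-quarter vectors are ordered NEW, WAXING, FULL, WANING). The same seed
always reproduces the same cohort, and fish are seeded individually so
enlarging a cohort never changes earlier fish.

## Typical analysis in Python

```python
import numpy as np
from otolunar import simulate, classify
from otolunar.residuals import fit_age_detrend
from otolunar.traits import extract_traits

params = simulate.default_params(n_spawned=800, seed=1, spawn_concentration=0.0)
series, truth = simulate.simulate(params)

model = fit_age_detrend(series)                      # pooled age detrend
X = np.array([extract_traits(s, model).as_array() for s in series])
y = [t.birth_quarter for t in truth]

acc, confusion, preds = classify.loocv(X, y, prior="equal")
print(acc, classify.adjacency_fraction(confusion))
```

## Notes

- The lunar clock is linear (synodic month 29.53 d by default), not an
  ephemeris; at quarter resolution the difference is below bin width.
- The published settlement-effect growth correction is *not* reproduced;
  `residuals.to_growth` exposes a correction hook (identity default).
- `scripts/acceptance.py` and the test suite generate all inputs
  programmatically; no data downloads are required.
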