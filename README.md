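# divevis

Tools for asking whether a diving seabird's foraging is constrained by how
far it can see underwater.  Given GPS tracks and time-depth-recorder (TDR)
records from a breeding colony, plus gridded covariates of underwater
visibility — Secchi-disc depth (Zsd, m; larger = clearer water), solar
elevation and cloud cover — the package reconstructs foraging trips,
detects dives and dive bouts, and fits two families of models:

* a **3-state hidden Markov movement model** (rest / area-restricted
  search / transit) on step lengths and turning angles, with transition
  probabilities that depend on water clarity:

  `Γ_ij(z) ∝ exp(β0_ij + βz_ij · z)` for `i ≠ j` (diagonal reference),

  fitted by direct maximization of the forward log-likelihood, compared
  with and without the Zsd covariate by AIC, decoded by Viterbi, and
  summarized as stationary/switching probability curves in `z`;

* **penalized-spline regressions (GAMMs)** for dive rate (negative
  binomial counts per 5-min fix, log link, AR(1) working correlation
  within trips) and dive depth (Gaussian maximum depth per bout), both
  built around a tensor-product smooth of solar angle × Zsd — the two
  variables jointly set light levels underwater — with cyclic time of
  day, cloud, water depth and random bird intercepts, REML-type smoothing
  selection with the γ = 1.2 complexity multiplier, and shrinkage bases
  so unsupported terms are regressed to ~0 effective degrees of freedom
  ("selected against") rather than formally dropped.

Because field data of this kind are not redistributable, the package
ships a first-class synthetic-data generator (`divevis.synthio`) that
emulates the study design — 5-min fixes, 0.5 Hz depth traces, daylight-
gated dives whose rate and depth follow a known solar × Zsd surface, a
fast/slow inter-dive mixture that creates bout structure, and lognormal
Zsd fields with mean 7.5 m and s.d. 2.6 m — along with the ground truth
needed to verify that every stage recovers what was put in.

## A worked example

```python
import numpy as np
from divevis import movehmm, synthio

truth = synthio.default_hmm_truth()
rng = np.random.default_rng(1)
data, states = synthio.simulate_hmm_dataset(truth, n_tracks=20, n_steps=400, rng=rng)

null = movehmm.fit_hmm(data, formula="null", n_restarts=1, seed=0)
fit  = movehmm.fit_hmm(data, formula="zsd", inits=null.params, n_restarts=1, seed=0)
```

prints (via `examples/04_movement_hmm.py`):

```
AIC: intercept-only 30959.9 vs +Zsd 30733.8 (delta 226.2; positive favours the Zsd model)
true transit->ARS slope 0.50/m, recovered 0.52/m
step means (km/5min): [0.08 0.7  2.96] vs truth [0.08 0.7  3.  ]
Viterbi decoding accuracy vs simulated truth: 98.0%
  P(transit->ARS | Zsd=4.0 m) = 0.011 [0.006, 0.015]
  P(transit->ARS | Zsd=7.5 m) = 0.061 [0.049, 0.073]
  P(transit->ARS | Zsd=11.0 m) = 0.279 [0.222, 0.335]
```

The ΔAIC of 226 says water clarity carries real information about state
switching; the slope 0.52/m against a simulated truth of 0.50/m is the
parameter-recovery check; and the last three lines are the fitted
switching curve — a bird in transit is ~25× more likely to drop into
area-restricted search over clear water (Zsd 11 m) than over turbid
water (Zsd 4 m).

The dive models read the same way (`examples/05_dive_models.py`): on
5 000 simulated fixes the fitted dive-rate model reports

```
               term    edf  statistic  p_value
te(solar_deg,zsd_m) 12.997     46.821      0.0
       s(cloud_pct)  0.000      0.000      1.0
    s(tod_h,cyclic)  4.036     52.884      0.0
  s(bird_id,random)  4.741     18.866      0.0
deviance explained 22.5%, presence AUC 72.8%
```

— the solar × Zsd surface and time-of-day are retained, the cloud term
(a true null in the generator) is shrunk to zero EDF, and the fitted
surface correlates with the generator's truth at r = 0.98.

The other examples cover simulation (`01`), track/trip processing (`02`),
dive and bout detection (`03`) and the end-to-end pipeline with its
markdown report (`06`).  A thin CLI wraps the shell-worthy entry points:

```sh
divevis simulate --seed 5 --out sim_dir
divevis run --seed 5 --out run_dir
divevis report run_dir
```

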