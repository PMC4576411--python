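# whaletrack

Fine-scale track reconstruction for tagged marine animals, built for
suction-cup archival tags (depth, tri-axial acceleration and magnetometry,
flow noise) deployed together with Fastloc-GPS loggers and boat-based visual
tracking. Dead-reckoning from the on-animal sensors gives movement detail at
1 Hz but drifts without bound; surface position fixes are accurate but
sparse and irregular. `whaletrack` fuses the two in a Bayesian state-space
model and reports position estimates with honest uncertainty.

## The model

Let *j* = 1..*J* index the position fixes at times *t_j*, with intervals
Δ*_j*. Given the initial position **x**₁, latent whale positions follow the
deterministic recursion

    x_{j+1} = x_j + d_j^dr + v_j^cor Δ_j

where **d**_j^dr = Σ *v_i* Δ*_i* is the dead-reckoned displacement over the
segment (1-Hz velocity *v_i* = *s_i* cos *p_i* (sin *h_i*, cos *h_i*) from
speed *s*, pitch *p* and compass heading *h*), and **v**^cor is a
velocity-correction term — the combined bias from water currents, sensor
error, and dead-reckoning assumption violations — modelled as a
non-directional Gaussian random walk,

    v_{j+1}^cor ~ MVN(v_j^cor, Σ Δ_j),   Σ = diag(σ_x², σ_y²).

Observation models are calibrated from dedicated accuracy tests and held
fixed during fitting:

* **Fastloc-GPS**: per-dimension scaled Student-*t* errors whose scale σ_q^F
  and shape ν_q^F depend on the number of satellites used (bins 4, 5, 6, 7,
  8, >8). Errors shrink and tails lighten with more satellites (from
  near-Cauchy at 4 satellites to near-Gaussian above 8).
* **Visual range**: Normal percent error, SD 30.2 % by eye, 10 % by laser
  range finder — `R_j ~ N(r_j, r_j σ_m^r/100)`.
* **Visual bearing**: wrapped Cauchy with concentration ρ = 0.897, linked to
  the state through `r_j = ‖x_j − x_j^b‖` and the four-quadrant arctangent
  bearing from the boat position `x_j^b`.

Priors: σ_x, σ_y ~ Unif(0, 0.1) m s⁻¹, initial correction components
~ Unif(−1, 1) m s⁻¹, and the initial position uses the error family of the
first observed fix. Fitting is MCMC (two chains, split R-hat ≤ 1.05
required); posterior draws of (**x**₁, **v**^cor, σ) are expanded into 1-Hz
posterior track realisations. See `docs/methods.md` for the sampler design
and numerical choices.

Coordinates are planar easting/northing metres in a transverse-Mercator
frame anchored at the first observed position; bearings are degrees
clockwise from true north in (−180°, 180°].

## Worked example

```python
import numpy as np
from whaletrack import simulate as sim, deadreckon as dr, ssm, calibrate as cal

ds = sim.simulate_dataset(sim.SimConfig(duration=7200), seed=2)
fixes = ssm.align_fix_times(ds.fixes)
v = ds.truth.dr_velocity()
times = np.unique(fixes.t)
d, delta = dr.segment_displacements(v, times)
post = ssm.fit_mcmc(fixes, d, delta,
                    cal.reference_gps_error_model(),
                    cal.reference_visual_error_model(),
                    config=ssm.McmcConfig(iterations=30_000, burn_in=10_000,
                                          thin=5, seed=0))
s = post.flat("sigma")
print("max R-hat", round(post.max_rhat, 3))
print("sigma_x mean", round(s[:, 0].mean(), 4))
tracks = ssm.posterior_track_realisations(post, v, fraction=0.10)
```

On this two-hour synthetic deployment (55 GPS + 33 visual fixes, true
σ_x = 0.014, σ_y = 0.012 m s⁻¹) this prints

```
max R-hat 1.006
sigma_x mean 0.0151
```

— the chains agree (R-hat well under the 1.05 gate) and the drift-SD
posterior centres near the generating value; the posterior-mean positions at
fix times sit ~12 m from the true track, against GPS errors of 8–34 m.
`tracks` holds 800 one-hertz track realisations whose spread is the
positional uncertainty.

The same pipeline is scriptable from the shell:

```
whaletrack simulate --seed 5 --duration 7200 --out run/
whaletrack preprocess --sensors run/sensors.csv --out run/sensors_1hz.csv
whaletrack fit --sensors run/sensors_1hz.csv --fixes run/fixes.csv --out run/
whaletrack crossval --sensors run/sensors_1hz.csv --fixes run/fixes.csv --out run/cv.csv
```

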