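# lemocot

Automated analysis of the **lower-extremity motor coordination test
(LEMOCOT)** performed on a pressure-sensor mat.

In the LEMOCOT a seated participant taps a proximal and a distal floor
target, 30 cm apart, alternately with the big toe, as fast and accurately
as possible for 20 s. The traditional score is the number of in-target
touches, counted by an examiner. Performed on an electronic mat (a grid of
small force sensors, e.g. 0.8 × 0.8 cm cells sampled at 60 Hz), the same
trial yields far more: every contact can be detected, located and
classified, turning a single count into a set of motor-performance
parameters relevant to clinicians and movement scientists studying
coordination after stroke.

## What it computes

From a force-frame recording the package extracts, per touch:

- **contact surface** — active-cell count × cell area (cm²);
- **endpoint** — the big-toe location, from the force distribution
  (force-weighted centroid of the cells near the target-most extreme of
  the contact);
- **COP** — the force-weighted mean position of the whole contact,
  COP = Σᵢ fᵢ pᵢ / Σᵢ fᵢ;
- **endpoint–COP distance** — congruence of the controlled point with the
  overall contact (a well-controlled toe touch keeps them close);
- **absolute error** — √((Xᵢ − X_target)² + (Yᵢ − Y_target)²), accuracy;
- **variable error** — √((Xᵢ − X̄)² + (Yᵢ − Ȳ)²) about the mean position
  of the same leg and target, consistency.

Touches are zoned on the y axis (a ±100 mm band around each target centre;
everything else is a *between-target* touch, typically a drag on the way to
a target) and classified in/out against a configurable target disc. The
statistical layer provides the analyses such a study needs: mixed-model
validation of the automated count against an examiner's count (slope,
intercept, conditional pseudo-R², limits of agreement), speed–accuracy
residualisation of error parameters on the in-target count using a
control-group prediction line, group × leg mixed models with Holm-adjusted
post hocs, and Spearman associations with clinical scores.

A fully seeded simulator renders synthetic trials (Gaussian contact blobs,
optional forefoot/heel contact, between-target drags, sub-threshold sensor
noise) with complete ground truth, so the whole chain is testable without
any instrument data.

## Worked example

```python
import lemocot as lm

cfg = lm.SimulationConfig(touch_rate_hz=1.8, endpoint_scatter_sd_mm=12.0,
                          p_between=0.1, seed=0)
rec, truth = lm.simulate_recording(cfg)

events = lm.extract_touch_events(rec)
metrics = lm.compute_touch_metrics(events, rec.layout)
summary = lm.summarize_trial(metrics, layout=rec.layout)

print("counts:", summary.counts)
print("traditional score:", summary.traditional_score)
print(f"mean surface: {summary.mean_surface_cm2:.2f} cm^2")
print(f"mean endpoint-COP distance: {summary.mean_endpoint_cop_distance_mm:.1f} mm")
print(f"mean absolute error (endpoint): {summary.mean_abs_err_endpoint_mm:.1f} mm")
print(f"mean variable error (endpoint): {summary.mean_var_err_endpoint_mm:.1f} mm")
print("truth counts:", truth.counts)
```

prints

```
counts: {'in': 35, 'out': 2, 'between': 6}
traditional score: 35
mean surface: 14.30 cm^2
mean endpoint-COP distance: 6.3 mm
mean absolute error (endpoint): 14.4 mm
mean variable error (endpoint): 13.8 mm
truth counts: {'in': 34, 'out': 3, 'between': 6}
```

The trial simulated 43 contacts at 1.8 touches/s with 12 mm endpoint
scatter; 35 landed inside the 25 mm-radius targets (the traditional score),
2 inside a target zone but off the disc, and 6 were between-target drags.
One touch whose true endpoint fell within a couple of millimetres of the
disc boundary is classified differently from the ground truth — endpoint
localisation on an 8 mm sensor grid is accurate to about one cell, so
labels at the boundary are uncertain by exactly that much (noiseless
simulations that keep endpoints away from the boundaries reproduce the
truth counts exactly; see `tests/test_acceptance.py`). The error means are
computed over the 37 in+out touches; drags are counted but carry no error
parameters.

The same pipeline is available from the shell:

```sh
lemocot simulate --out trial/ --seed 0
lemocot score trial/recording.txt --out scored/
lemocot validate --table cohort.csv --out validation/
lemocot stats --table cohort.csv --dv abs_err_ep_mm --residualize --out models/
```

Every output directory contains a `run_manifest.json` (config snapshot,
input hashes, package version, seed) from which the run can be reproduced.

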