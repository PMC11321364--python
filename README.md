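# pulseoxmc

Monte Carlo modelling of how skin pigmentation biases transmittance
finger pulse oximetry.

Pulse oximeters estimate arterial oxygen saturation (SpO₂) from the
ratio of ratios

    R = (AC/DC at 660 nm) / (AC/DC at 940 nm),

where AC/DC = (I_d − I_s)/I_s is the pulsatile fraction of the
transmitted intensity between diastole and systole, via a linear
calibration SaO₂ = a + b·R (a widely used commercial relation is
SpO₂ = 110 − 25·R).  Because melanin absorbs red light far more
strongly than infrared, epidermal pigmentation can shift the
R-to-SaO₂ relation and make a single calibration overestimate
saturation in darkly pigmented subjects — the mechanism behind
clinically observed occult hypoxemia.

`pulseoxmc` provides, for researchers in biomedical optics and
physiological measurement:

- a layered **finger tissue model** (six skin sublayers, fat, muscle
  with an embedded bone cylinder, 13 mm total) with wavelength-resolved
  optical properties driven by melanosome volume fraction
  (2.55%/15.5%/30.5% for Fitzpatrick types I/IV/VI), blood oxygen
  saturation and cardiac phase;
- a seeded, weight-conserving **Monte Carlo photon transport engine**
  (hop–drop–spin, Henyey–Greenstein scattering, Fresnel surfaces,
  Russian roulette, geometric splitting, correlated condition
  families);
- **calibration analytics**: AC/DC tables, ratio-of-ratios curves by
  ordinary least squares, bias tables against the commercial relation,
  and skin-tone correction multipliers;
- an **experiment pipeline** and CLI covering the full
  3 phenotypes × 7 saturations × 2 phases × 2 wavelengths grid, plus a
  deterministic analytics path that runs entirely from packaged
  published tables.

## Worked example

The deterministic analytics reproduce the published closed-form results
without any simulation:

```python
from pulseoxmc.experiment_pipeline import analytics_from_fixtures

res = analytics_from_fixtures()

print(res.bias["light"].to_table().to_string(index=False))
print("mean light bias:", round(res.bias["light"].mean_bias, 1))
print({k: round(v, 2) for k, v in res.multipliers.items()})
print("clinical cohort bias ratio:",
      res.cohort["bias_ratio_from_printed_means"])
```

prints

```
 sao2  spo2  bias
 86.0  87.8   1.8
 87.0  88.8   1.8
 88.0  89.8   1.8
 89.0  90.7   1.7
 90.0  91.7   1.7
 91.0  92.7   1.7
 92.0  93.6   1.6
mean light bias: 1.7
{'moderate_linear_at_100': 1.23, 'dark_linear_at_100': 1.65, 'dark_mean_of_profile': 1.79}
clinical cohort bias ratio: 6.6
```

Reading: a light-skin subject whose true saturation is 89% would be
displayed as 90.7% by the commercial relation (bias +1.7%).  Scaling
the moderate-skin curve's R by 1.23 aligns it with the light-skin
curve; the dark-skin curve needs the mean of an effectively exponential
multiplier profile, ≈1.8.  The clinical cohort shows mean biases of
0.5% (White) and 3.3% (Black) — a ratio of 6.6.

A scaled-down simulated experiment (about a minute on one CPU):

```python
from pulseoxmc.experiment_pipeline import (
    ExperimentConfig, run_grid, assemble_tables,
)

config = ExperimentConfig.from_preset("ci", seed=1)
result = assemble_tables(run_grid(config), config)
for skin, curve in result.curves.items():
    print(skin, round(curve.intercept, 1), round(curve.slope, 1))
```

Equivalent CLI:

```bash
pulseoxmc paper-tables --out out/deterministic
pulseoxmc simulate --preset ci --seed 1 --out out/simulated
```

See `docs/methods.md` for the model, its estimators, and a documented
discrepancy between this simulator and the published phenotype
separation of the calibration curves.

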