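# waxshelix

Helical structural descriptors of double-stranded RNA from solution
small- and wide-angle X-ray scattering (SWAXS) profiles.

A SWAXS curve I(q) is a 1-D, orientationally averaged fingerprint of a
molecule in solution.  For short RNA duplexes its periodic features encode
the helical geometry — but many structural parameters (helical radius,
groove widths) live on similar length scales, so reading the geometry off
the curve directly is hard.  `waxshelix` treats the problem as supervised
regression in momentum space: generate a large synthetic ensemble of
duplex conformations with known geometry, compute their scattering exactly,
and train gradient-boosted tree ensembles to invert the map

    log10 I(q_1), ..., log10 I(q_K)   ->   radius, twist, rise,
                                           major-groove width,
                                           A-form fraction.

Trained models are then applied to noisy, experimental-style curves by
Monte-Carlo sampling, yielding a *distribution* of descriptor predictions
whose mode is the robust point estimate.

It is aimed at scattering/structure people who want a desk-scale,
fully synthetic, end-to-end reproduction of this modelling strategy —
no molecular-dynamics trajectories or beamline data required.

## What is inside

| module | role |
|---|---|
| `helix_forge` | coarse-grained (3 beads/residue) 12-bp RNA duplex generator: helical radius, 11 per-step twists/rises, per-step A-like vs compact form flags, bead jitter; PDB + manifest I/O |
| `descriptors` | the five supervised labels, extracted from bead coordinates: cylinder-fit axis, radius, twist, rise, spline-smoothed major-groove width, A-form class 0..11 |
| `scattering` | exact Debye-sum profiles on the 191-point q grid (0–0.95 Å⁻¹, 0.005 Å⁻¹ spacing), the nine KCl/MgCl₂ solution conditions, buffer-subtraction offset fitting with propagated errors |
| `dataset_builder` | labeled feature matrices, conformation-grouped 68/17/15 splits with a held-out-hash leak guard, noise injection, q-resampling, random-label control; HDF5 + CSV |
| `boosted_models` | per-descriptor XGBoost regressors + 12-class A-form classifier; five training variants, grouped 10-fold CV, learning/noise/under-sampling studies, linear baselines, gain/weight importance traces |
| `noisy_inference` | Gaussian profile sampling at error levels α (presets low/medium/high = 0.2/1.0/2.0), prediction distributions with histogram, mode, mean, sd |
| `profiles_io`, `pipeline`, `cli` | 3-column profile text format, one-config YAML pipeline, `waxshelix` command line |

## Worked example

```python
from waxshelix import helix_forge, descriptors, scattering, \
    dataset_builder, boosted_models, noisy_inference

# canonical fiber A-RNA reference geometry
canonical = helix_forge.canonical_aform()
print(descriptors.describe(canonical))

# small end-to-end run: forge -> scatter -> label -> split -> train
models = helix_forge.sample_ensemble(300, seed=1)
ds = dataset_builder.assemble(models)                  # 300 x 9 = 2700 rows
ds = dataset_builder.split_by_conformation(ds, seed=1)
config = boosted_models.TrainingConfig(n_trees_final=400,
                                       early_stopping_patience=50)
bundle = boosted_models.train(ds, "radius", config)
print(f"radius model: test MSE = {bundle.report['test_mse']:.4f} A^2, "
      f"R^2 = {bundle.report['test_r2']:.3f}")

# Monte-Carlo error propagation through the trained model
target = models[5]
profile = scattering.debye_profile(target)
profile.sigma = 0.02 * profile.intensity               # 2% synthetic errors
features = noisy_inference.sample_noisy_profiles(profile, "medium",
                                                 n=5000, seed=1)
dist = noisy_inference.predict_distribution(bundle, features, alpha=1.0)
print(f"true radius  = {descriptors.describe(target).radius:.2f} A")
print(f"mode = {dist.mode:.2f} A, mean = {dist.mean:.2f} A, sd = {dist.sd:.2f} A")
```

prints

```
DescriptorVector(radius=9.4, twist=32.69999999999998, rise=2.8099999999999987,
                 major_groove_width=8.69999369879137, aform_class=11)
radius model: test MSE = 0.0305 A^2, R^2 = 0.926
true radius  = 9.04 A
mode = 8.96 A, mean = 8.92 A, sd = 0.08 A
```

The canonical A-form duplex reproduces its calibration values (radius
9.4 Å, twist 32.7°, rise 2.81 Å, major groove 8.7 Å, all 11 steps A-like).
A 300-conformation model already recovers held-out radii to ±0.17 Å; at
the production ensemble size (thousands of conformations) held-out R²
reaches ~0.97.  The Monte-Carlo distribution for one 2%-error profile at
the medium error level places its most probable radius within 0.1 Å of the
generating truth, with the spread quantifying how the experimental errors
propagate through the non-linear model.

The same pipeline is available from the shell:

```bash
waxshelix forge --n 100 --seed 1 --out ensemble/
waxshelix score ensemble/*.pdb --out descriptors.csv
waxshelix scatter ensemble/conf000000.pdb --out profiles/
waxshelix run --out full_run/          # forge -> ... -> 25 trained bundles
waxshelix predict --model full_run/models/radius__noise-free \
    experiment.dat --alpha medium --out predictions.csv
```

See `docs/methods.md` for the model conventions, parameter defaults and
known limitations.

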