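# Methods

This note documents the models, conventions, defaults and limitations of
`waxshelix`: a fully synthetic pipeline that learns to read helical
structural descriptors of a 12-base-pair RNA duplex out of solution X-ray
scattering (SWAXS) curves.

## 1. The synthetic duplex ensemble

### Geometry

Each conformation is generated from a latent `HelicalParameterSet`: a
phosphate radius r (Å), eleven per-step twists Ω_k (deg) and rises h_k
(Å), eleven binary step-form flags (A-like vs *compact*), and a per-bead
jitter scale.  Beads are placed on an ideal helical scaffold: base pair i
sits at axial height z_i = Σ h_k and frame azimuth φ_i = Σ Ω_k.  Every
residue contributes three beads:

* **phosphate** at radius r,
* **sugar** at radius r − 2.9 Å under the phosphate azimuth,
* **base** displaced d Å from the axis into the wide inter-backbone gap
  (d = 4.0 Å for A-like steps, 1.5 Å for compact ones; 4.4 Å for the
  canonical fiber reference).

Bead electron counts are sums of atomic numbers of the atoms assigned to
each bead (phosphate 47 e⁻; sugar 53 e⁻; base 69/77/57/57 e⁻ for
A/G/C/U); the table and atom assignment are documented in
`helix_forge.py`.  Terminal-residue chemistry is not modelled, so total
electron count is constant across conformations of a sequence.  The
default sequence is the 12-mer 5′-CCUCCUAAUCGC-3′ with its complement.

**Strand phase and backbone lead.** The two antiparallel phosphate
backbones are offset in azimuth by a strand-phase constant (406.043°,
mod 360°) and each leads the base-pair frame by ±2.5 × (mean twist) along
its own chain direction — the phosphate bridges adjacent residues, so its
azimuth advances with the local winding.  The two constants were
calibrated jointly and then frozen so that

1. the canonical A-form duplex (r = 9.4 Å, Ω = 32.7°, h = 2.81 Å)
   evaluates to a major-groove width of **8.7 Å**, the geometric
   calibration point, and
2. groove width is *monotone increasing in twist*: unwinding narrows the
   major groove, over-winding widens it, the direction experimentally
   established for dsRNA (divalent ions unwind, compress, and tighten the
   major groove).  A twist-independent strand phase produces the opposite
   direction in any cylindrical backbone model, which is why the
   twist-coupled lead is a structural necessity here, not a free
   ornament.

### Step-class setpoints

A-like steps use twist 32.7°, rise 2.70 Å, displacement 4.0 Å; compact
(non-A) steps use 28.0°, 2.33 Å, 1.5 Å — an unwound, axially compressed,
base-centered geometry.  Duplex contour lengths (11 × mean rise) under
the default sampler therefore span ≈ 25.6–29.7 Å, the plausible range for
a 12-bp duplex in solution.  Classic B-DNA setpoints (rise 3.38 Å) were
deliberately not used for the non-A class: they would stretch the duplex
to ~37 Å and do not describe the compacted non-A states dsRNA actually
visits.

### Sampling defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| ensemble size | 5000 (pipeline default) | thousands of conformations × 9 conditions ≈ 5 × 10⁴ curves |
| radius | U(8.5, 10.5) Å | ±1 Å around the fiber value |
| per-step twist | setpoint ± U(2.0°) | bounded so zero-jitter step classification is unambiguous |
| per-step rise | setpoint ± U(0.12 Å) | same bound argument (half the setpoint gap is 0.185 Å) |
| A-step propensity p | U(0, 1) per duplex; flags ~ Bernoulli(p) | covers all 12 A-fraction classes |
| bead jitter | 0.25 Å Gaussian | thermal-fluctuation scale of a coarse bead |

These defaults *are* the study conditions of every statistical claim in
the test suite; they were fixed before the recovery experiments and not
revisited afterwards.

What the generator emulates: a structurally diverse duplex ensemble whose
five descriptors vary independently enough to be learned, with bead-level
disorder.  What it does not emulate: sequence-dependent fine structure,
base-pair fraying, cooperative (spatially correlated) A↔compact
transitions, explicit solvent/ion scattering, and single-stranded or
non-duplex species.  Conclusions from passing tests therefore concern the
machine-learning pipeline's ability to invert a known, well-posed
structure–scattering map — not the fidelity of any real RNA ensemble.

## 2. Descriptor extraction

Labels are always computed from bead coordinates, never from generator
latents (the latents are retained only for round-trip tests).

* **Axis** — best-fit cylinder through the 24 phosphates (Gauss–Newton on
  the spread of point-to-line distances, initialized from a PCA of the
  base-pair phosphate midpoints).  Exact on ideal helices.
* **Radius** — mean perpendicular phosphate distance from the axis.
* **Twist / rise** — per-strand phosphate azimuth increments projected
  perpendicular to the axis, averaged over both strands; axial separation
  of successive base-pair centers.  Mean twist < 0 (a left-handed mirror
  image) raises a `ChiralityError`.
* **Major-groove width** — minimal cross-strand phosphate–phosphate
  distance over densely sampled, *smoothing-spline* backbone traces
  (regularization λ = 2.0), restricted to pairs whose midpoint lies on
  the far side of the axis from the base beads (the major groove).  The
  raw distance is reported; no phosphate van-der-Waals diameter is
  subtracted — under the subtracted convention the compact-state widths
  (~3–7 Å) would go negative, and the canonical 8.7 Å anchor is
  consistent with the raw convention.  λ was selected by maximizing the
  label's test–retest reliability across independent jitter realizations
  (reliability ≈ 0.92 at λ = 2 vs 0.86 unsmoothed), a criterion
  independent of any downstream model score; the strand-phase calibration
  absorbs the smoothing bias so the canonical value stays 8.7 Å.
* **A-form class** — per-step threshold on the base displacement from the
  axis (midpoint between the A and compact setpoints, 2.75 Å), measured
  from the two base beads of the pair that opens the step; steps inside a
  ±0.5 Å ambiguity band fall back to the step-rise midpoint threshold.
  Base displacement is the canonical A-vs-non-A discriminator and is
  measured ~10× more robustly than step rise at the default jitter, which
  keeps the discrete label stable (zero flips across jitter redraws) while
  still recovering latent flags exactly on zero-jitter models.

## 3. Scattering

Profiles are exact Debye double sums over all 72 beads,
I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sinc(q dᵢⱼ), with a Gaussian bead form factor
fᵢ(q) = Zᵢ exp(−(q r_b)²/2), r_b = 2.5 Å by default.  The q = 0 limit is
handled analytically (sinc(0) = 1); no histogram or sampling
approximation is used at this size.  The default grid is 191 points,
q = 0.000–0.950 Å⁻¹ at 0.005 Å⁻¹ spacing; grid construction refuses
non-divisible ranges instead of silently truncating.

**Solution conditions.** The nine documented buffers (30/50/100/200/500
mM KCl; 0.25/0.5/1.0/5.0 mM MgCl₂) are modelled parametrically:
I_cond(q) = I(q)·(1 + ε·exp(−(q/0.2 Å⁻¹)²)) + b, a small ion-cloud
contrast modulation concentrated at low q plus a flat buffer-subtraction
residual.  ε grows in magnitude with ionic strength (opposite sign for
the divalent series) and b is a few counts.  Amplitudes were calibrated
once so that the additive offset c fitted between any two conditions of
one conformation stays below 10% of I(q_max) with a ≈ 2× margin
(measured maximum ≈ 5–6% across seeds); this reproduces the statistical
footprint of real buffer-subtraction mismatch without explicit solvent
modelling.

**Offset fitting.** c minimizes Σⱼ [I(qⱼ) + c − I_exp(qⱼ)]²/σ′(qⱼ)²; the
closed form is the σ′-weighted mean residual.  The propagated error σ′
defaults to the experimental σ itself; the propagation rule is injectable
(`propagate_error(rule=...)`) because instruments differ in how the
signal-to-noise ratio enters — only the weights change, never the
closed form.

## 4. Dataset and models

Features are log₁₀ of the condition-modulated intensities (base 10 is a
documented convention; monotone transforms are immaterial to trees).
Rows = conformations × conditions; labels are computed once per
conformation and replicated.  Splits (68/17/15) shuffle *conformations*,
never rows, because the nine condition profiles of one duplex are
near-replicates; split sizes use floor rounding with the remainder to
training.  The test rows are hashed at split time and the hash is
re-verified before every final evaluation; datasets derived by noise
injection, resampling or label randomization re-freeze their own test
hash at derivation.

Boosted ensembles use the histogram tree method, single-threaded for
determinism.  Centralized defaults (config-overridable): learning rate
0.1, max depth 6, L2 = 1, L1 = 0, leaf penalty 0, 7500 trees with
early-stopping patience 50 for final models, 750 trees for 10-fold CV,
which is conformation-grouped like the main split.  The regression loss
is squared error; the A-form task uses a 12-class softmax with
cross-entropy (classes observed at training time are encoded contiguously
and predictions decoded back).  Five variants per descriptor: noise-free,
noisy (5% multiplicative training noise, S/N = 20, training rows only),
sparse (100 q points), dense (400 q points), and the random-label
control (labels redrawn uniformly over their observed domains).
Importance traces (gain and weight) are mapped to q by column index into
the stored grid and normalized to sum to 1.

**Problem sizes used by the test suite.** The statistical property suite
runs on a 2000-conformation ensemble (18 000 rows) with up to 800 trees,
and the trace studies (learning curve, noise levels 7–30%, under-sampling
across the Shannon limit n_s = q_max·D_max/π ≈ 10) on a 600-conformation
slice with 150 trees over three seeds — sizes at which every trend the
suite asserts is already stable.  The pipeline default remains 5000
conformations × 7500 trees.

## 5. Noisy inference

Each experimental point is treated as a draw from an independent normal
law N(I_exp(qⱼ), α·σ(qⱼ)); α presets low/medium/high = 0.2/1.0/2.0.
Draws are taken from the positive-truncated normal (equivalent to
redrawing negative intensities), because the log feature is undefined at
I ≤ 0 and all n curves are kept; truncation materially reshapes the
high-q law only at α = 2.  The default n = 5000 sampled profiles, with a
warning below 1000.  Histograms use the Freedman–Diaconis rule with a
50-bin fallback for degenerate inter-quartile ranges; mode ties break
toward the smaller value; for the classifier the histogram is the class
frequency table.  The mode is the recommended point estimate — an
injected 5% gross-outlier contamination moves the mean visibly but not
the mode.

## 6. Known limitations

* **Major-groove recovery sits just under R² = 0.9.** The groove label is
  a minimum over smoothed backbone traces and inherits bead jitter that
  the orientationally averaged Debye profile cannot see; its test–retest
  reliability (~0.92 under default jitter) bounds attainable held-out R²,
  and the trained model reaches ≈ 0.89–0.90.  Reducing the jitter or
  further smoothing the label would lift the number but change the study
  conditions, so the bound is reported rather than engineered away.
* **Exact A-form class accuracy is ~0.55, not high.** With independently
  sampled step forms, distinct step *arrangements* within one class
  produce genuinely overlapping profiles; the exact 12-way count is
  information-limited even on noise-free data.  The fraction itself is
  well recovered — ~95% of held-out predictions fall within ±1 class
  (mean absolute error ≈ 0.5 classes).  Ensembles with cooperative
  (blockwise) form transitions, as molecular dynamics produces, would
  make the count nearly 1-D and much easier.
* **Training noise at 5% acts as augmentation here.** On smooth synthetic
  profiles, multiplicative training noise slightly *improves* clean
  validation error for every descriptor; degradation appears, and grows
  monotonically, over the 7–30% noise study together with the widening
  train–test gap (the overfitting signature).
* The condition model is a two-parameter caricature of ion–solvent
  contrast; it reproduces the offset statistics, not ion-specific
  scattering physics.
* Ridge regression at exactly zero penalty differs numerically from
  ordinary least squares on the strongly collinear log-profile features;
  the equivalence holds on well-conditioned designs (covered as such in
  the tests).
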