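# Methods

`saxsshape` answers one question: given a 1D small-angle X-ray scattering
curve I(q) from a dilute, isotropic aqueous suspension of nanoparticles
measured on a laboratory instrument, which of nine form-factor models best
describes the particles?  It does so by simulating labelled training data,
transforming curves into latent spaces, and benchmarking classifiers on top.
This note records the model, the numerical choices, and what the synthetic
data do and do not capture.

## Scattering model

A particle population is described by a shape class, geometric parameters
(lengths in Å), X-ray scattering length densities (SLD, units 1e-6 Å⁻²) for
core, shell and solvent, a volume fraction φ, and a relative polydispersity.
The nine classes are the homogeneous sphere, cylinder, prolate and oblate
ellipsoids of revolution, and their shelled counterparts: core-shell sphere,
hollow sphere (core SLD equals the solvent), core-shell cylinder (shelled on
sides and ends), core-shell prolate and core-shell oblate.

Oriented amplitudes use the standard analytic kernels.  With
Φ(x) = 3[sin x − x cos x]/x³:

* sphere: F = Δρ V Φ(qR);
* cylinder (angle α between axis and q):
  F = Δρ V sinc(qL cos α / 2) · 2J₁(qR sin α)/(qR sin α);
* ellipsoid of revolution: F = Δρ V Φ(q r(α)) with
  r(α) = [R_e² sin²α + R_p² cos²α]^{1/2};
* core-shell: contrast-weighted difference of two homogeneous amplitudes,
  F = (ρ_core − ρ_shell) V_core f_core + (ρ_shell − ρ_solv) V_outer f_outer.

Isotropy is imposed by averaging |F|² over orientations with sin α weight,
computed by Gauss–Legendre quadrature in u = cos α.  The base order is 76;
for elongated particles the integrand oscillates with phase ≈ q(d_max −
d_min), so the order grows as 64 + 1.2·q_max·(d_max − d_min), capped at
1000.  A doubling check (`check_convergence=True`) flags non-converged
quadratures with a warning.

Polydispersity is a Gaussian in the overall size — all linear dimensions
scale together — truncated at ±3σ (and at zero, with renormalisation and a
warning).  The size average uses an 11-node Gauss–Legendre rule on the
truncated interval reweighted by the Gaussian density; the test suite checks
it against a 1e5-sample Monte-Carlo average to 0.5%.  Absolute intensity
follows the φ·⟨|F|²⟩/⟨V⟩ convention with the single 1e-4 constant converting
(1e-6 Å⁻²)²·Å³ to cm⁻¹.

## Instrument model

Two laboratory configurations are built in, with the grids that give a fixed
890-point input:

| | Xeuss1800HR | NanoInXiderHR |
|---|---|---|
| q_min (Å⁻¹) | 0.85e-4 | 3.74e-4 |
| q_max (Å⁻¹) | 1511e-4 | 4527e-4 |
| Δq (Å⁻¹) | 1.7e-4 (890 pts) | 7.5e-4 (604 pts) |
| beam FWHM (Å⁻¹) | 0.0016 | 0.0024 |
| flux (ph/s) | 3.43e6 | 7.22e6 |
| counting time | 20 min | 20 min |

The Xeuss grid is defined by its 890 points; the step then equals
(1511 − 0.85)e-4/889 ≈ 1.7e-4.  The nominal sample-to-detector q-ranges
(0.0031–0.1493 and 0.0019–0.4452 Å⁻¹) are kept in config metadata.

A measurement is: model intensity on the native grid → Gaussian convolution
in q at the beam FWHM (reflect padding, so no intensity is lost at the
Guinier end) → per-bin Poisson counting noise.  Expected counts are
λ_j = I_j · flux · time · k with a single per-configuration solid-angle
factor k calibrated so that a flat water-like background of 0.016 cm⁻¹
collects ~200 counts per bin in 20 min; reported uncertainties are
σ_j = sqrt(counts)/(flux·time·k).  Dark current, cosmic spikes and
buffer-subtraction residuals are not modelled — real curves contain them,
and the real-data protocol (q > 0.005 Å⁻¹ truncation) exists precisely
because such low-q artifacts are outside the simulation.

## Synthetic datasets

The sampler draws, per curve: sizes log-uniformly (spheres/cores 10–1000 Å;
cylinder radii 10–300 Å with lengths log-uniform in [4R, 5000 Å]; ellipsoid
reference radii 10–400 Å with elongation uniform in (1, 6]); shell thickness
uniform in 10–50% of the smallest core dimension; core SLD log-uniform
12–120, shell 11–60 (re-drawn until |shell−core| ≥ 2 and |shell−water| ≥ 1,
water = 9.47); volume fraction log-uniform 1e-4–5e-3 (dilute, structure
factor ≈ 1); polydispersity uniform in [0, 0.2].  These ranges cover the
1–100 nm window the instruments resolve and keep every class physically
plausible; they are collected in one constants block so they can be revised
against a reference dataset.

Four builds exist: single-configuration (DS_X, DS_N), DS_mix (each noiseless
curve assigned to one of the two configurations by deterministic alternation
after a seeded shuffle — an exact half/half split) and DS_all (each noiseless
curve rendered in both configurations, twice the size from the same pool).
NanoInXider curves are capped at q_max = 0.1511 Å⁻¹ — their high-q tail is
noise-dominated — and linearly oversampled onto an 890-point grid, so every
stored curve has the same input length J = 890.  Seeds fully determine a
dataset; noise streams are keyed by (seed, model index, configuration) so
that the Xeuss half of DS_all is bit-identical to DS_X.

Low-q truncation for real-data work removes bins with q ≤ 0.005 Å⁻¹; with
per-configuration grids the retained length is the largest common suffix, so
the matrix stays rectangular (exact for single-configuration data, at most a
few extra bins removed in mixed sets).

## Preprocessing

Five operators compose left-to-right: TH (threshold at 1e-15 cm⁻¹), LOG
(natural log; the pipeline refuses LOG without an earlier TH), STD (per-bin
standardisation), IntN (division by the invariant ∫ I q² dq, trapezoid rule
on the native grid), and QLOG (resampling onto a log-spaced grid with exact
endpoints and unchanged length — the paper-style "condense the high-q
decades" step; the resampled length is kept at J since no other length is
mandated).  IntN must precede LOG, since the invariant is defined on
linear-scale intensities.  The preset `"best"` is TH∘IntN∘LOG∘STD∘QLOG.

STD statistics are fitted on training folds only and frozen for test folds.
A formulation that standardises over the full dataset would leak test-set
statistics into training; the leakage-free variant costs a little accuracy
but makes the cross-validation honest, and the canary test (a label-encoding
feature injected only into held-out data must not raise accuracy) guards it.
STD is fitted on whatever grid precedes it in the chain.

## Representations

* **Guinier fit / Rg.**  An automated window search over ln I vs q²: from a
  small set of candidate origins the window grows while the self-consistency
  condition q·Rg ≤ 1.3 holds, and the best-linearity fit (R² ≥ 0.98) wins.
  Curves with no valid window — notably cylinders much longer than 1/q_min,
  where a gyration radius is not meaningful — raise an error and are
  excluded from the Kratky feature spaces.  This is a self-contained
  re-implementation of the usual automated-Guinier idea, not a port of any
  specific tool.
* **Kratky-integral (Franke-style) features.**  V′(x) = 2π² I(0) /
  [Rg³ ∫₀^{x/Rg} q² I dq], a dimensionless normalised apparent volume, with
  I(0) and Rg from the Guinier fit and the [0, q_min] gap covered by the
  Guinier extrapolation.  V′ is evaluated at 5 (or 200) points linearly
  spaced in qRg ∈ [3, 7] and concatenated with Rg → 6 (or 201) features.
  Any affine variant of V′ carries the same classification information; this
  normalisation is pinned in one function.  Cylinder-like classes are
  excluded by a label filter.
* **PCA at 90% variance** (scikit-learn, full SVD): the latent dimension is
  whatever the preprocessed training fold requires.
* **Supervised CNN encoder**: conv64k7 → conv64k7 → maxpool6 → dropout 0.25
  → conv64k7 → conv256k7 → maxpool6 → dropout 0.25 → global max pool, then a
  9-way softmax perceptron.  The encoder's 256-vector is the latent space;
  it is detachable and reusable with any classifier.  In (I, q) mode the
  input has two channels, with q scaled by the common 0.1511 Å⁻¹ cap.  The
  network is implemented in NumPy (shifted-GEMM 1D convolutions, exact
  gradients verified against finite differences), trained with Adam on
  categorical cross-entropy; inference is deterministic (dropout off).
* **Convolutional auto-encoder** (optional, experimental): conv/pool encoder
  to a 200-dim latent, mirror decoder with nearest-neighbour upsampling,
  Adam on MSE.  The input is cropped to a multiple of 36 (890 → 864) so the
  two pool-6 stages invert exactly.

## Benchmark protocol

A method is preprocessing ∘ representation ∘ classifier, with classifiers
KNN (Euclidean, k=5), random forest (500 trees), gradient-boosted trees
(XGBoost, 500 rounds, depth 6, learning rate 0.1) and the CNN's own softmax
perceptron (PL, only meaningful with the CNN representation).  Defaults are
exposed as hyperparameters.  Evaluation is repeated stratified 5-fold
cross-validation; every repeat re-draws the split and re-seeds all learners
with derived seeds (seed + r), and methods compared on the same seed share
fold splits, so per-repeat accuracies are paired.  Two methods are compared
with a two-sided Wilcoxon rank-sum test at α = 0.01 on their per-repeat
accuracies.  `folds_per_repeat` optionally evaluates only the first m folds
of each repeat — the split is still 5-fold stratified — which is how the
neural representations are benchmarked at reduced scale.

The transfer experiment trains one method per dataset build (DS_X, DS_N,
DS_mix, DS_all) and tests on held-out single-configuration data, giving the
4×2 table whose diagonal-high / off-diagonal-collapse structure measures how
poorly rules learned on one instrument transfer to the other, and how mixed
training restores generality.

Real-data scoring: per labelled sample, +1 for an exact prediction, 0 for an
"informative" confusion (a geometrically adjacent form factor), −1
otherwise; totals over 10 samples lie in [−10, +10].  The informative map is
symmetric: sphere↔{prolate, oblate}, prolate↔oblate, and the shelled family
core-shell sphere↔{core-shell prolate, core-shell oblate, hollow sphere},
core-shell prolate↔core-shell oblate, hollow sphere↔{core-shell prolate,
core-shell oblate}.  For the classes the published protocol leaves
unspecified the same similarity logic is extended: cylinder↔prolate (nearest
homogeneous neighbour) and core-shell cylinder↔core-shell prolate.  KNN ties
are broken toward the smallest class index (scikit-learn's convention),
fixed for reproducibility.

## Problem sizes and numerical choices

Full-scale runs (4184 curves per class, 890-point input, 20 repeats) are
supported through the CLI and are overnight jobs on a workstation.  The
shipped test suite and the acceptance script run the same protocol at desk
scale.  Two reductions keep them there: fewer curves (150/class in the
suite, 120/class in the acceptance script, 20/class for the transfer
tables), and a 3x-subsampled input grid (J = 297) for the benchmark — the
native Δq oversamples the beam FWHM about nine-fold, so every third bin
retains the resolved information while cutting network cost threefold.  The
scaled CNN recipe is 60 epochs at batch size 32 and learning rate 3e-3: with
only a few hundred training curves the full-scale defaults (50 epochs, batch
128, lr 1e-3) yield a handful of gradient steps per epoch and leave the
network far from converged.  `CNNClassifier.fit` also supports early
stopping on a held-out validation slice with best-weight restore; it is off
by default at reduced scale, where a ~100-curve validation slice is noisy
enough to stop training well before the latent space is useful.

At these scales absolute accuracies sit far below the full-scale figures —
a few hundred training curves cannot saturate nine classes spanning wide
parameter ranges — and the margin of the supervised CNN latent space over a
strong raw-intensity random forest is a large-sample property: in our runs
the CNN space trails the forest below roughly 10³ training curves, reaches
parity around 10³, and the decisive advantage belongs to the 10⁴-curve
regime.  What the scaled runs do establish is the rest of the structure:
learned methods far above chance, raw-space KNN trailing the tree
ensembles, diagonal-dominant configuration transfer, chance-level accuracy
after label shuffling, and the near-spherical aspect-ratio confusion dip.

Other numerical choices: float32 throughout the network; He initialisation
seeded per model; Adam with default rates (1e-3, 0.9/0.999); a non-finite
training loss aborts with a diagnostic; degenerate STD bins (zero variance)
are centred but not scaled, with a warning; IntN refuses non-positive
invariants; QLOG refuses q₀ ≤ 0 (truncate first); curve resampling refuses
extrapolation.

## What the synthetic data do not show

The generator reproduces grid, smearing and counting statistics of the two
devices, but not instrument backgrounds, aggregation artifacts, buffer
mismatch or beam-damage trends.  Passing the suite therefore demonstrates
that the pipeline learns and transfers form-factor structure under realistic
noise — not that a model trained here will classify any particular
laboratory sample; the simulated "real-like" scoring in the acceptance
script quantifies self-consistency, not field performance.  The exact noise
pipeline of the vendor software the study data came from is proprietary;
per-bin Poisson counting is an approximation to it.
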