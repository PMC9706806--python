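# Methods

## The measurement model

The simulator emulates differential pulse voltammetry of a four-electrode
array — MIP(CFX), MIP(LFX), MIP(MFX) and a nonimprinted NIP control — over a
+0.6…+1.5 V window sampled at 114 points (the grid size is configurable; a
5 mV instrument step would give 181 points, and nothing else in the pipeline
depends on the choice).

For sensor *s* and analyte *a*, the bound-analyte response follows a one-site
Langmuir isotherm

    h_{s,a}(C) = B_{s,a} · C / (k_{s,a} + C)        [μA]

with saturation response `B` (μA) and dissociation constant `k` (μM). Each
analyte contributes a Gaussian oxidation peak of height `h` at its
characteristic peak potential, and peaks superpose additively on the
baseline:

    i_s(E) = baseline_s(E) + Σ_a h_{s,a}(C_a) · exp(−(E − E_a)²/2w²) + ε(E)

Assumptions worth stating explicitly: no competitive binding between
analytes (additivity), symmetric Gaussian peak shapes, and a baseline that
does not depend on the analytes. Electron-transfer kinetics, diffusion and
matrix effects are out of scope.

### Default sensor bank

`B_max` values (1–12 μA) encode the class selectivity pattern: each of the
CFX and LFX imprints responds most strongly to its own template, the NIP
responds least to every analyte, and MFX draws intrinsically smaller currents
than the other two on every electrode (so MIP(MFX) is only mildly dominant
for its template). The bank also carries entries for flumequine (FLQ) and
nalidixic acid (NA) so the five-class discrimination study can run.

`k_D` defaults lie at 400–800 μM — *above* the 2–300 μM working domain, with
the own-template sensor always having the highest affinity (smallest k_D).
This weak-saturation regime is a deliberate design point: the response is
visibly hyperbolic over the domain (roughly 30–40% saturated at 300 μM, so
Langmuir fits recover both parameters), yet the whole range up to 300 μM
remains analytically usable, which is what a wide detection range means in
practice. Had k_D sat inside the domain (say 60 μM), the top half of the
range would be flat and nearly information-free, and no regression method —
neural or otherwise — could interpolate the strongly curved inverse map from
a 3-level factorial design.

Peak potentials (CFX 1.00, LFX 0.94, MFX 1.08, FLQ 1.20, NA 1.25 V) are
plausible placements chosen so current maxima fall at distinct potentials;
peak width defaults to 0.07 V (FWHM ≈ 165 mV), broad enough that 12 DCT
coefficients reconstruct every default trace with R² ≥ 0.999 (see below).
None of these values are measurements; all are configurable per sensor.

Baselines default to sensor-specific straight lines (intercept 0.4–0.6 μA,
slope 0.25–0.40 μA/V). An exponential anodic rise (solvent-oxidation wall)
is implemented and can be enabled per sensor; it is off by default because
the residual any *nonlinear* baseline component leaves after the two-edge
linear correction has nonzero edge slopes, and such a residual's DCT decays
only algebraically — near-blank corrected traces then stop compressing to 12
coefficients at high fidelity (R² plateaus near 0.997).

### Noise

Measurement noise per trace: per-point additive Gaussian (σ = 0.06 μA, i.e.
0.5% of the largest default B_max), per-point relative Gaussian (1% of the
clean current) and an optional per-trace constant drift offset (default 0).
This is a conservative stand-in for the high-single-digit %RSD repeatability
regime of real MIP arrays. All noise is seeded; an array measurement spawns
one independent substream per sensor, and a dataset uses one substream per
sample, so every simulation is exactly reproducible.

## Designs

The training design is the full crossing of per-factor level sets:
arithmetic sequences over each analyte's range, shifted by per-factor "tilt"
offsets (defaults 0, +3%, −3% of the range, clipped to the range) so no two
analytes share identical level sets — this decorrelates the design matrix.
With 3 levels and 3 factors this yields the 27 training mixtures; the
external test set draws each concentration uniformly from its range with a
fixed seed. The tilt magnitudes are bounded by half the inter-level spacing
so level ordering is preserved.

## Signal processing

Baseline correction subtracts the straight line fitted to the first and last
`n_edge = 10` points. Compression keeps the first *k* = 12 coefficients of
the orthonormal type-II DCT (low-pass, fixed layout — a prerequisite for a
fixed ANN input dimension; orthonormality gives Parseval and a clean
truncation-error story). `choose_k` finds the smallest *k* reaching a target
reconstruction R² on a trace set; on default zero-noise traces spanning the
concentration domain it returns 11, so the conventional 12 is comfortable.
Features are concatenated sensor-major in canonical (sorted sensor_id)
order: 4 × 12 = 48 values. Traces are corrected before compression; a switch
allows compressing raw traces instead.

## Calibration

`fit_langmuir` is a bounded least-squares fit with deterministic
initialization (B₀ = 1.1·max h; k₀ from interpolating the monotonized curve
at B₀/2). The limit of detection uses the conventional LOD = 3σ_blank/S with
S = B_max/k_D, the isotherm's initial slope (a 3.3σ variant is available).
The reported working range is [LOD, C at 90% saturation], capped at the
largest measured concentration. Note the low-concentration log-linear fit is
reported but genuinely log-linear behavior holds near k_D (the inflection of
h vs log C), not far below it, where the isotherm is linear in C.

## Discrimination

PCA mean-centers (no autoscaling by default — DCT coefficients share μA
units; a switch enables it) and decomposes by SVD; loading signs are fixed
(largest-magnitude element positive) so score plots are reproducible. Class
ellipses use the known-covariance χ²₂ form: semi-axes √(λ_i q) with q the
χ²₂ quantile at the chosen level; the small-sample F-form is not used, a
choice that matters little at the default 8 replicates per class. Ellipse
overlap is decided numerically on 720 boundary points.

## Quantification ANN

Topology (48, 7, 3) with logistic-sigmoid hidden and tanh output units.
Because tanh is bounded, targets are scaled per analyte into [−1, 1] with a
wide margin (default `output_margin = 1.0`, placing scaled targets within
±1/3, where tanh deviates from linearity by < 4%). A narrow margin (e.g.
10%) parks the extreme training targets at ±0.9 in tanh's saturating zone
and measurably warps interpolation between factorial nodes. Inputs are
scaled through one shared affine map over all 48 coefficients (10% margin):
per-dimension min–max scaling would amplify noise-dominated high-order
coefficients to O(1) amplitude and degrade generalization under noise.

Training minimizes full-batch MSE in scaled space with L-BFGS
(`max_epochs = 2000`, relative-decrease tolerance `1e-9`) from a
Nguyen–Widrow hidden-layer initialization (weight rows of norm
0.7·h^(1/n_in) with biases spread across the input range — the classic
choice for sigmoid function approximation) and a small uniform output layer.
Everything is seed-determined, runs are bit-reproducible, and the returned
loss never exceeds the initialization loss; hitting the epoch cap returns
the best-so-far parameters with a logged warning. Topology search is seeded
k-fold (default 3) cross-validation on total NRMSE *inside the training
subset only*, ties going to the smaller network; the external test set never
informs selection.

Evaluation: per analyte, ordinary least squares of predicted on expected
(slope, intercept, R² as squared Pearson correlation), plus
NRMSE = √(Σ(ĉ−c)²/Σc²) aggregated over all samples and analytes — the
normalization by Σc² is this package's documented convention.

## What the synthetic study does and does not show

Passing tests demonstrate that the *pipeline* is correct and that, under the
stated measurement model — additive Gaussian peaks, Langmuir saturation, 1%
noise, no drift or matrix effects — the DCT–ANN recovers mixture
concentrations (testing R² ≥ 0.96, NRMSE ≈ 0.03 at the default seed) and
DCT–PCA separates the five analyte classes. They do not certify performance
on real instrument data, which adds peak-shape asymmetry, potential shifts,
electrode fouling and drift, inter-electrode variability and real matrix
effects; the synthetic %-variance figures (e.g. PCA explained variance) have
no claim to match any instrument's.

## Problem sizes and determinism

The default study (27 + 10 samples × 4 sensors × 114 points, one ANN fit)
runs in well under a second; the full test suite, including Monte-Carlo
coverage checks (2·10⁴ points) and a 100-seed Langmuir robustness sweep,
completes in a few seconds. One master seed is split by `SeedSequence` into
named substreams (test-set draw, train/test/calibration/PCA noise, ANN
initialization, CV folds), so stages can be reproduced in isolation from the
run log.
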