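# Methods

`nucleophys` quantifies two complementary physicochemical readouts of
nucleoli in live cells — local macromolecular density via the refractive
index (RI) of optical-diffraction-tomography (ODT) volumes, and local
fluidity via the diffusion coefficient of probe proteins measured by
fluorescence correlation spectroscopy (FCS) — together with the
synthetic-data generators that stand in for instrument data and provide
exact ground truth for every analysis step.

## RI tomogram phantoms

A phantom is a voxel grid (axis order `(z, y, x)`, coordinates in um
from the grid corner) rendered from an ordered list of ellipsoidal
compartments over a uniform medium.  Assignment is by voxel-center
test: a voxel's noiseless RI is the RI of the last listed compartment
whose ellipsoid contains the voxel center, which makes ground-truth
masks exact by construction rather than approximate, at the price of
ignoring partial-volume effects at boundaries.  Defaults encode the
compartment contrasts reported for live HeLa cells: medium 1.337,
cytoplasm and nucleoplasm 1.349, nucleoli 1.363, with nested
sub-nucleolar shells placeable at user-chosen RI steps.

The voxel size defaults to (0.356, 0.11, 0.11) um.  Instrument vendors
do not publish their reconstruction grid spacing; these values are
stand-ins at the scale of the axial/lateral optical resolution of a
typical ODT system and are configurable everywhere.  Tomogram noise is
modelled as additive i.i.d. Gaussian RI noise per voxel (default SD 0;
0.001 is used as a realistic level in noisy fixtures, i.e. an order of
magnitude below the nucleolus–cytoplasm contrast of 0.014).  Real
tomograms additionally carry structured artifacts (missing-cone
elongation, reconstruction ripple) that the phantom does not emulate,
so passing tests demonstrate correctness of the quantification
pipeline, not robustness to reconstruction artifacts.

The reference fixture `five_nucleoli_cell` contains five spherical
nucleoli with diameters 2.1–3.0 um plus one 1.5 um distractor sphere at
nucleolar RI, so that the high-RI band forms six connected components of
which exactly five survive the ≥ 2 um rule.

## RI-band segmentation and quantification

Segmentation assigns each voxel to the first band whose half-open
interval `[lo, hi)` contains its RI — half-open so that boundary values
break ties deterministically — and extracts 26-connected components per
band.  "Under 2 um" is operationalised as the equivalent spherical
diameter computed from component volume, `d = (6V/pi)^(1/3)`; components
below 2 um in the nucleolar band are not counted as nucleoli.  Volumes
are voxel counts times the (possibly anisotropic) voxel volume.

Two mean-RI estimators are shipped.  The band-median estimator
`(lo+hi)/2` reproduces the rendering-based workflow in which the
midpoint of the transfer-function band is read out as the compartment's
mean RI; the voxel-mean estimator averages the actual RI values under a
mask and serves as the oracle.  When the mask is drawn from the band
the two can differ by at most half the band width.

Time-lapse series are summarised per frame (band-median RI, voxel-mean
RI, volume per band) with endpoint percent changes
`100*(after-before)/before` (the earlier frame is the denominator) and
the nucleolus-to-cytoplasm fold-ratio of the RI percent changes.  With
one fixed band set the percent change is computed on the voxel-mean
series (a fixed band has a fixed midpoint); when per-frame band sets
are supplied — mirroring the practice of re-tuning rendering bands as
the cell changes — the band-median series is used instead.  On the
printed ATP-depletion endpoint pairs (nucleolus 1.364 → 1.376,
cytoplasm/nucleoplasm 1.348 → 1.354) the implementation yields 0.88%
and 0.45%; published roundings of the same pairs (0.90%/0.42%) differ
slightly at the second decimal and the fold-ratio robustly rounds to 2
either way, so no attempt is made to force agreement beyond the
fold-ratio.

## FCS trace simulation

Point emitters take i.i.d. Gaussian steps with per-axis SD
`sqrt(2 D dt)` in a periodic cubic box and are detected through a 3D
Gaussian profile with lateral 1/e² radius `w` and structure parameter
`s = z/w`; detected intensity is the brightness-weighted sum over
particles, optionally gated by a two-state bright/dark telegraph
process (equilibrium dark fraction `T`, relaxation time `tau_T`) that
realises triplet blinking, plus optional Poisson shot noise.  Because
sampled Brownian positions are exactly Gaussian increments, the
expectation of the trace autocorrelation is exactly the fitted model;
recovery tests are therefore consistency checks, not approximations.

Particle number is fixed at `round(c * box³)` with
`c = N / V_eff`, `V_eff = pi^(3/2) w² z`, rather than Poisson-resampled
per run — a deliberate deviation from open-volume reality that lowers
run-to-run variance in desk-scale recovery studies.  The box (default
3 um, minimum 6 w enforced) is small enough that a particle can wrap
around and re-enter the detection region, and the axial profile decays
to ~1% (not zero) at the boundary for the default `w = 0.2 um, s = 5`;
both effects bias the correlation at the percent level, well inside the
recovery tolerances used.  Instrument parameters (`w`, `s`, brightness,
count rates) are conventional confocal values carried in configuration,
not measured values.

The inner loop is JIT-compiled and draws normals from a 128-layer
Marsaglia–Tsang ziggurat over a splitmix64 counter — an exact sampler
(validated by KS test and tail counts against N(0,1)) chosen because
general-purpose generators were the simulation bottleneck.  Gaussian
weights are skipped beyond a lateral cutoff where they fall below
~2e-11.  Replicate measurements derive independent child seeds from the
spec seed; every stochastic operation in the package is explicitly
seeded.

## Autocorrelation

Curves use the "+1" convention `G(tau) = <dF dF>/<F>² + 1` with the
global trace mean.  The direct estimator sums products at an explicit
integer lag list in O(n·k) and is the oracle.  The multi-tau estimator
(block size m = 16, first lag dt, truncation at duration/4) computes
lags 1..16 on the raw series, then 9..16 on successively pairwise-binned
series; a binned estimate at lag `k·2^l` equals a triangularly weighted
average of direct autocorrelations over the bin window (up to
end-of-trace truncation O(b/n)), which is the equivalence the tests
verify — at unbinned lags the two estimators agree to machine
precision.

## Model fitting and calibration

The fitted model is

    G(tau) = 1 + Tr(tau)/N * sum_i y_i (1 + tau/tauD_i)^-1 (1 + tau/(s² tauD_i))^-1/2,
    Tr(tau) = (1 - T + T e^(-tau/tau_T)) / (1 - T),

the standard 3D free-diffusion form; the triplet factor is the
conventional completion of a model usually quoted without it.  Fits are
(optionally replicate-SD-weighted) Levenberg–Marquardt with multi-start:
diffusion-time starts on a 6-point log grid across the lag range (all
ordered pairs for two components), keeping the best local optimum;
failure of every start raises an explicit error, never silent defaults.
The structure parameter defaults to fixed `s = 5.0`, standard practice
when no calibration measurement fixes it; fitting `s` freely is
available.  Replicate curves are averaged pointwise before fitting with
their per-point SD attached, which measurably reduces parameter scatter
versus single-replicate fits.

Model order (1 vs 2 components) is decided by a nested F-test on
residual sums of squares at alpha = 0.05, the conventional choice where
no explicit criterion is documented; ties and degenerate cases fall
back to one component.  When the 1-component residual is already at the
machine-precision floor (noise-free curves) the F-test is skipped — a
ratio of two round-off residuals carries no information — and one
component is kept.  Diffusion times convert to coefficients by
`tauD = w²/(4D)` or, bypassing `w`, by referencing rhodamine 6G
(`D = 280 um²/s`): `D = D_ref · tau_ref/tau_probe`.  In the nucleolus,
the slow (smaller-D) component of a two-component fit is reported as
the characteristic mobility — the fast component is attributed to probe
not interacting with the dense phase; in other compartments the
fraction-weighted mean is reported with both components retained.

## Condition statistics

Long-format per-cell tables (condition × compartment × metric) are
summarised as mean, SD, SEM = SD/√n and n.  Conditions are compared to
a baseline by a two-sided Student's pooled-variance t-test at
alpha = 0.05 (Welch behind a flag; unpaired assumed, as pairing is not
documented for this design), with percent change of group means and a
significance flag; no multiple-testing correction is applied and raw
p-values are reported.

## Problem sizes and numerical choices

Simulation studies in the test suite use 20 independent 10 s
measurements at dt = 2 us (5e6 samples, ~240 particles) per scenario —
the full measurement protocol length; the acceptance script uses 12
seeds per scenario, a size at which the reported fractions and means
are stable to well inside their tolerances.  Correlator-equivalence
checks use 1e5-sample traces, and the exact triangular-average identity
is verified on 2e3-sample traces where the full window sum is cheap.
Degenerate inputs fail loudly: zero-mean traces have no defined
normalization, empty masks no mean RI, zero baselines no percent
change, and sub-minimum boxes are rejected rather than silently biased.

## Known limitations

No optical forward model (diffraction, missing cone) on the ODT side;
no photobleaching, confinement, anomalous diffusion or detector
afterpulsing on the FCS side; band limits for real tomograms remain
user inputs, as published band limits are shown graphically, not
numerically.  The package quantifies; it does not attribute sub-band
volumes to specific sub-nucleolar compartments.
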