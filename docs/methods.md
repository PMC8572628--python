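# Methods

This note records the models implemented, the assumptions behind them,
the defaults and why they were chosen, and what the simulation does and
does not show about real scanner data.

## Scope and forward model

Everything is 2-D, single-slice, parallel-beam and monoenergetic. The
object is an attenuation map μ(x, y) in mm⁻¹ on a square pixel grid;
Hounsfield units relate to attenuation by HU = 1000·(μ/μ_w − 1) with
μ_w = 0.02 mm⁻¹, a representative water value at abdominal-CT effective
energy. The coordinate convention, fixed once and used by every module,
is: physical origin at the grid centre, x right, y up, array element
(0, 0) the top-left pixel, pixel spacing = field of view / grid size.

A scan is a set of view angles uniform over [0°, 180°) with a centred
uniform detector array per view. The system matrix Z stores, for every
ray c and pixel k, the exact intersection length Z_kc (mm) of the ray
with the pixel, computed by incremental (Siddon-style) traversal of the
plane crossings. This makes the forward model Y_c = Σ_k Z_kc μ_k an
exact line integral of the piecewise-constant image, testable against
independent chord-length geometry; the matrix is kept sparse (CSR).

Fan-beam or helical geometry, scatter, beam hardening, finite focal
spot, detector cross-talk and tube-current modulation are deliberately
out of scope: the reconstruction algebra is geometry-agnostic and a
parallel-beam model keeps both reconstructors standard and exactly
analysable.

## Phantom

The synthetic abdomen is a layered list of ellipses (later entries
overwrite earlier ones, the Shepp–Logan convention): a subcutaneous-fat
oval (−90 HU, outer semi-axes 105 × 85 mm), a soft-tissue body
(40 HU, 92 × 72 mm), a liver (77 HU) and a gallbladder (55 HU), on air
(−1000 HU) inside a 220 mm field of view. Organ HU values sit at
typical portal-phase abdominal readings so the simulated ROI statistics
are on a clinically plausible scale. Pixel membership is decided by
pixel-centre containment with no anti-aliasing — rasterisation is then
exact and deterministic, and region masks partition the grid.

The phantom emulates only first-order region statistics (mean HU of
uniform organs). It has no texture, no heterogeneity, no partial-volume
blur at acquisition, and no patient-to-patient variability, so passing
tests demonstrate algorithmic behaviour (bias, noise, convergence), not
diagnostic image quality on real anatomy.

## Noise model and the noise index

Detector noise is photon-counting: transmitted counts are Poisson with
mean N₀·exp(−Y_c), and the noisy projection is −log(max(N,1)/N₀)
(zero-count bins clamped to one count before the log, the standard
guard against infinities). For large counts the projection variance is
approximately exp(Y_c)/N₀ (delta method), which the tests verify by
Monte Carlo. Electronic noise and detector non-idealities are ignored.

Scanners specify dose through a *noise index* (NI) rather than photon
counts. Here NI is defined as the target standard deviation, in HU, of
a water-equivalent background ROI in the FBP reconstruction.
`calibrate_counts` maps NI to N₀ by bisection on log-counts over
simulated flat-field acquisitions: a uniform water oval with the outer
dimensions of the default abdomen (48% × 39% of the field of view) is
projected, noised, FBP-reconstructed, and the central-ROI SD (averaged
over three fixed noise realisations) is driven to the target. The
calibration object matches abdominal attenuation on purpose: the
reconstructed noise level depends strongly on how much the object
attenuates, so calibrating on a smaller or less attenuating object
would systematically underestimate the photon budget an abdomen needs.
Background SD is monotone decreasing in N₀, so bisection converges; 14
bisection steps on a 10²–10⁹ bracket resolve N₀ far below the Monte
Carlo noise of the SD estimate itself. Acquisition settings such as kV
and mAs are carried as run metadata only — no dose physics is attached
to them.

## Filtered back projection

Each view is convolved with the band-limited discrete ramp kernel
(h[0] = 1/4s², zero at even lags, −1/(πms)² at odd lags m, s the
detector spacing), implemented in the frequency domain as the exact DFT
of that kernel with zero padding to the next power of two ≥ twice the
detector count (avoiding circular wrap-around). The kernel's small
residual DC component (order 1/n of the ramp peak) is retained: it
compensates kernel truncation, and removing it shifts the whole
reconstruction by tens of HU. Apodization windows: none ("ramp"), Hann
(default) or Hamming; Hann is the common soft-tissue clinical choice
and gives stable noise behaviour for method comparisons.
Back projection weights each view by π/n_angles and samples the
filtered profile at t = x·cosθ + y·sinθ by linear interpolation.

On a noiseless 360-view scan of a 60 HU disk (256² grid) this pipeline
recovers the central ROI mean to well under 1 HU and an interior RMSE
near 1 HU, and it agrees with scikit-image's independent `iradon`
implementation to about 1.5 HU mean absolute difference inside the
object.

## Iterative reconstruction

The iterative core is the simultaneous algebraic technique. With
current image R, measured projections Y and residuals Φ = Y − Z·R, the
per-pixel correction is

    E_k = λ · [ Σ_c Z_kc · (Φ_c / Σ_j Z_jc) ] / [ Σ_c Z_kc ]

— each ray's residual is first normalised by that ray's total chord
length, then averaged over all rays through the pixel with
intersection-length weights (SART normalisation). This normalisation
was chosen over formulations with reciprocal weights 1/Z on individual
rays, which are dimensionally unstable when a ray barely clips a pixel;
averaging length-normalised ray errors is the form that is provably
stable for λ ∈ (0, 2). Pixels crossed by no ray receive no correction.
All pixels update simultaneously (R ← R + E), attenuation is clamped
non-negative after each update (physical constraint, standard in
iterative reconstruction), and the loop stops when the relative L2
image change drops below the tolerance (default 10⁻⁴) or the iteration
budget runs out (class default 50). The loop contains no randomness, so
reconstructions are bit-reproducible.

Properties verified by the tests: exact data is a fixed point for any
relaxation, blend and init; on consistent systems the residual norm is
non-increasing for λ ∈ (0, 1]; on random consistent full-column-rank
systems the converged iterate matches the dense pseudoinverse
least-squares solution to ≤ 10⁻³ (observed ~10⁻¹²). On rank-deficient
systems the limit depends on the starting image and need not be the
Euclidean minimum-norm solution, which is why the oracle comparison is
restricted to full-rank systems.

**Initialisation and the comparison protocol.** The default *comparison*
protocol starts the loop from a zero image and runs 20 iterations at
λ = 1 with no FBP blending. An FBP start is available (and is the
natural choice on noiseless, consistent data, where it converges in one
step), but for noisy data it transfers FBP's high-frequency noise into
the iterate, and an unregularised algebraic loop cannot remove it: the
forward operator is nearly blind to high-frequency image components, so
their corrections are vanishingly small. Started cold, the loop
recovers low and mid frequencies first and the iteration count acts as
the regulariser — at 20 iterations the organ means are within a few HU
of truth while the organ SD is roughly a third of FBP's. Run much
longer on noisy data the iterate semi-converges toward the noisy
least-squares solution and the noise returns (organ SD roughly doubles
between iteration 20 and 50), which is why the noisy protocol stops
early while noiseless runs simply iterate to convergence (the thin
peripheral fat ring is the slowest structure, needing ~100–200
iterations to settle).

**Blending.** The final image may be a convex combination
blend·iterative + (1−blend)·FBP, emulating the percentage levels at
which commercial adaptive statistical iterative reconstruction mixes
its result with FBP. The default is 1.0 (pure iterative), since no
particular commercial percentage is being reproduced.

## Image-quality metrics

CT value = arithmetic mean HU over the ROI; SD = sample standard
deviation (n−1 denominator — the scanner-console convention; no
estimator is universally documented); SNR = CT/SD, reported rounded to
two decimals with full precision retained. Repeated measurement is
modelled as seeded integer-pixel jitter of the ROI mask (default three
placements, ±2 px), mirroring manual re-placement; CT and SD are
averaged and SNR recomputed from the averages. ROIs derived from
phantom region labels are eroded by 3 px by default so partial-volume
boundary pixels stay out of the statistics, as a radiologist would
place an ROI well inside an organ. Because "background noise" is
sometimes read in the organ and sometimes in subcutaneous fat, the
default comparison reports both organ-ROI SD and fat-ROI SD, labelled
by region.

## Default problem sizes

The standard comparison runs on a 256² grid (the clinical 512² matrix
scaled down to keep a full matrix build, calibration and five-seed
comparison in well under a minute on one core), 180 views, 365 detector
bins at pixel pitch covering the field-of-view diagonal, NI 24, 20
iterations. The oracle suites use 2×2/3×3-pixel systems with ≤ 16 rays
where dense linear algebra is exact. Grid size, view count and all
physics parameters are plain config fields, so the 512² setting is one
config line away (the system matrix build scales roughly with
views × detectors × grid size).

## Known limitations

- Parallel-beam, monoenergetic, 2-D only; no scatter or beam hardening.
- The NI ↔ counts mapping is a simulation-level stand-in for a
  proprietary scanner dose-control loop; only its qualitative role
  (one knob controlling reconstructed background SD) is claimed.
- The iterative loop is unregularised; its denoising comes entirely
  from early stopping, not from a statistical noise model or prior, so
  absolute SD ratios depend on the iteration budget.
- Uniform-ellipse phantoms cannot exhibit texture-dependent effects
  (e.g. the waxy appearance of aggressive iterative reconstruction on
  real anatomy).
- DICOM support is read-only and minimal (pixel data, rescale
  slope/intercept, pixel spacing).
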