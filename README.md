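# ctrecon

Simulated CT reconstruction for studying how an algebraic iterative
reconstruction loop compares with filtered back projection (FBP) on
abdominal-style scans: phantom simulation, exact forward projection,
photon-counting noise with a scanner-style noise index, both
reconstructors, and the ROI image-quality metrics radiologists report
(CT value, SD, SNR).

It is aimed at people who want a small, fully inspectable sandbox for
the classic clinical claim about iterative reconstruction — *same scan,
less noise, higher SNR, unchanged CT values* — without access to scanner
raw data.

## The methods in brief

**Forward model.** A 2-D attenuation image *R* (pixels *k*, mm⁻¹) is
probed by parallel-beam rays *c*; the system matrix *Z* holds the exact
ray–pixel intersection lengths computed by Siddon-style traversal, so a
measured projection is the line integral *Y<sub>c</sub> = Σ<sub>k</sub>
Z<sub>kc</sub> R<sub>k</sub>*. Noise: transmitted counts are Poisson
with mean *N₀ exp(−Y<sub>c</sub>)* and the noisy projection is
−log(*N*/*N₀*). The noise index NI is calibrated to be the background SD
(HU) of the FBP reconstruction of an abdomen-sized water oval.

**FBP baseline.** Per-view ramp filtering (band-limited discrete kernel,
optional Hann/Hamming apodization, FFT with power-of-two zero padding)
followed by linearly interpolated back projection with the π/*n*<sub>angles</sub>
quadrature weight.

**Iterative loop.** Starting from an initial image *R⁰*, each iteration
computes estimated projections *Y\*<sub>c</sub> = Σ<sub>k</sub> Z<sub>kc</sub>
R<sub>k</sub>*, projection errors *Φ<sub>c</sub> = Y<sub>c</sub> −
Y\*<sub>c</sub>*, and the length-normalised, ray-averaged per-pixel
correction

&nbsp;&nbsp;&nbsp;&nbsp;*E<sub>k</sub>* = λ · [Σ<sub>c</sub> Z<sub>kc</sub>
(*Φ<sub>c</sub>* / Σ<sub>j</sub> Z<sub>jc</sub>)] / [Σ<sub>c</sub> Z<sub>kc</sub>],

then updates *R<sub>k</sub> ← max(R<sub>k</sub> + E<sub>k</sub>, 0)*
simultaneously for all pixels (the SART scheme). The loop stops when the
relative L2 image change falls below a tolerance or the iteration budget
runs out; the result can be blended with the FBP image to emulate
percentage-style adaptive statistical iterative reconstruction levels.

**Metrics.** For a region of interest: CT value = mean HU, SD = sample
standard deviation (noise), SNR = CT / SD, with seeded ROI-jitter
averaging to emulate triplicate manual measurement.

## Worked example

`examples/03_fbp_vs_iterative.py` reconstructs one noisy simulated scan
of the built-in abdominal phantom with both methods and prints:

```
   method         roi  ct_hu  sd_hu  snr
      FBP       liver  76.44  18.90 4.04
      FBP gallbladder  57.50  18.18 3.16
      FBP        body  40.00  17.80 2.25
iterative       liver  78.58   9.97 7.88
iterative gallbladder  55.48   8.90 6.23
iterative        body  42.28  12.54 3.37

iterative loop ran 20 iterations; final residual norm 6.202
```

Reading: both methods reconstruct the same noisy sinogram. CT values
(mean HU) agree with the phantom truth (liver 77 HU, gallbladder 55 HU,
body 40 HU) to a few HU for both methods, so neither biases tissue
density. The iterative reconstruction roughly halves the organ noise
(SD) at matched dose, which doubles the SNR — the ordering reported for
clinical adaptive statistical iterative reconstruction. The other
examples demonstrate phantom construction, the forward/noise model, and
the noise-index → photon-count calibration.

A thin CLI wraps the same pipeline:

```bash
ctrecon compare -o out/                 # full comparison, default config
ctrecon phantom-render --size 512 -o phantom.tiff
ctrecon project -c my.yaml -o sino.raw
ctrecon reconstruct -i sino.raw --method asir --iters 20 --init zero -o rec.raw
ctrecon measure -i rec.raw --roi liver --roi gallbladder
```

## Layout

- `src/ctrecon/phantom.py` — ellipse phantoms, rasterisation, region masks
- `src/ctrecon/projection.py` — geometry, system matrix, forward projection, noise, NI calibration
- `src/ctrecon/fbp.py` — filtered back projection
- `src/ctrecon/asir.py` — the iterative reconstruction loop
- `src/ctrecon/metrics.py` — ROI CT/SD/SNR and comparison tables
- `src/ctrecon/io.py`, `pipeline.py`, `cli.py` — formats, config, end-to-end runs, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
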