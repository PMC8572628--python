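"""The headline experiment: FBP vs iterative reconstruction of one noisy scan.

Both methods reconstruct the SAME noisy sinogram of the abdominal
phantom. The table lists, per region of interest, the CT value (mean HU),
SD (noise, HU) and SNR = CT/SD. The iterative reconstruction should show
clearly lower organ SD and higher SNR than FBP at matched dose, while the
CT values of the two methods stay close - the same ordering reported for
adaptive statistical iterative reconstruction on clinical scanners.
"""

import logging

from ctrecon import run_comparison
from ctrecon.io import load_config

logging.basicConfig(level=logging.INFO, format="%(message)s")

# 128-pixel grid keeps this demo quick; incident counts given explicitly
# to skip the noise-index calibration step
config = load_config(None, {
    "size": 128,
    "n_angles": 120,
    "noise.incident_counts": 5.0e4,
    "noise.seed": 1,
    "rois": ["liver", "gallbladder", "body"],
})
result = run_comparison(config)

print()
print(result.table[["method", "roi", "ct_hu", "sd_hu", "snr"]]
      .round(2).to_string(index=False))
print(f"\niterative loop ran {result.convergence.iterations} iterations; "
      f"final residual norm {result.convergence.residual_norms[-1]:.3f}")
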