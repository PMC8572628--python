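"""Map a scanner-style noise index to incident photons per detector bin.

The noise index (NI) is treated as the target standard deviation, in HU,
of a water-equivalent background region in the FBP reconstruction.
Calibration bisects on the incident counts of a simulated abdomen-sized
water oval until the reconstructed background SD hits the target. Higher
NI means fewer photons (lower dose) and noisier images.
"""

from ctrecon import (
    FBPConfig,
    NoiseModel,
    ScanGeometry,
    add_noise,
    build_system_matrix,
    calibrate_counts,
    default_abdomen_spec,
    fbp_reconstruct,
    forward_project,
    hu_to_mu,
    render_phantom,
)
from ctrecon.metrics import measure_roi, roi_from_label

size = 128
spec = default_abdomen_spec()
geometry = ScanGeometry.for_image(size, spec.field_of_view, n_angles=120)
matrix = build_system_matrix(geometry, size, spec.field_of_view / size)
clean = forward_project(hu_to_mu(render_phantom(spec, size)), matrix)
fbp_cfg = FBPConfig("hann", size, spec.field_of_view / size)
body = roi_from_label(spec, "body", size, erode=2)

for ni in (14.0, 24.0):
    counts = calibrate_counts(ni, matrix)
    noisy = add_noise(clean, NoiseModel(ni, counts, seed=0))
    sd = measure_roi(fbp_reconstruct(noisy, fbp_cfg), body).sd_value
    print(f"NI {ni:4.0f} -> {counts:9.3g} photons/bin -> "
          f"phantom body SD {sd:5.1f} HU")
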