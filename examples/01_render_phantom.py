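"""Build the default abdominal phantom and inspect its labelled regions.

The phantom is a layered ellipse model on a 220 mm field of view: a
subcutaneous-fat oval (-90 HU) enclosing a soft-tissue body (40 HU) that
contains a liver (77 HU) and a gallbladder (55 HU), on an air background.
The printed means confirm each region rasterises to exactly its assigned
Hounsfield value.
"""

from ctrecon import default_abdomen_spec, region_mask, render_phantom

spec = default_abdomen_spec()
image = render_phantom(spec, size=256)

print(f"field of view: {spec.field_of_view} mm, "
      f"pixel spacing: {image.pixel_spacing:.3f} mm")
for label in ("fat", "body", "liver", "gallbladder"):
    mask = region_mask(spec, label, 256)
    area_cm2 = mask.sum() * image.pixel_spacing**2 / 100.0
    print(f"{label:>12}: mean {image.pixels[mask].mean():7.1f} HU, "
          f"area {area_cm2:6.1f} cm^2")
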