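"""Shared fixtures. The expensive 256-pixel system matrices are
session-scoped so the pipeline, FBP and acceptance tests share them."""

from __future__ import annotations

import numpy as np
import pytest

from ctrecon import (
    Ellipse,
    PhantomSpec,
    ScanGeometry,
    build_system_matrix,
    forward_project,
)
from ctrecon.io import load_config


@pytest.fixture(scope="session")
def default_config():
    """Default comparison config: 256 px, 180 views, NI 24, seed 0."""
    return load_config(None)


@pytest.fixture(scope="session")
def matrix_256_180(default_config):
    """System matrix for the default 256-pixel, 180-view geometry."""
    cfg = default_config
    return build_system_matrix(cfg.geometry, cfg.size, cfg.pixel_spacing)


@pytest.fixture(scope="session")
def disk_setup_256_360():
    """Noiseless 360-view sinogram of a centred 60 HU, 40 mm disk (256 px)."""
    from ctrecon import hu_to_mu
    from ctrecon.phantom import render_phantom

    spec = PhantomSpec(
        ellipses=(Ellipse(0.0, 0.0, 40.0, 40.0, 0.0, 60.0, "disk"),),
        field_of_view=220.0,
    )
    image = render_phantom(spec, 256)
    geom = ScanGeometry(360, 363, 220.0 * np.sqrt(2.0) / 362, 220.0)
    matrix = build_system_matrix(geom, 256, image.pixel_spacing)
    sinogram = forward_project(hu_to_mu(image), matrix)
    return spec, image, matrix, sinogram
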