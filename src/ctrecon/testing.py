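"""Synthetic tiny tomographic systems for validation and benchmarking."""

from __future__ import annotations

import numpy as np

from .phantom import ImageGrid
from .projection import ScanGeometry, Sinogram, SystemMatrix, build_system_matrix, forward_project

__all__ = ["make_consistent_system"]


def make_consistent_system(
    rng: np.random.Generator, full_rank: bool = True
) -> tuple[SystemMatrix, Sinogram, np.ndarray, np.ndarray]:
    """Random tiny tomographic system with consistent (noiseless) data.

    Samples a 2x2 or 3x3 grid and a small parallel-beam geometry (at most
    16 rays), builds the exact intersection-length system matrix, and
    forward-projects a random positive attenuation image, so the returned
    sinogram is exactly consistent with the returned image. When
    ``full_rank`` is set, geometries whose matrix has deficient column rank
    are resampled, making the least-squares solution unique.

    Returns ``(matrix, sinogram, dense_weights, mu_true)``.
    """
    while True:
        size = int(rng.integers(2, 4))
        n_angles = int(rng.integers(3, 6))
        n_det = int(rng.integers(size + 1, 6))
        if not size * size <= n_angles * n_det <= 16:
            continue
        geom = ScanGeometry(n_angles, n_det, size * 1.5 / n_det, float(size))
        matrix = build_system_matrix(geom, size, 1.0)
        dense = matrix.weights.toarray()
        if not (dense.sum(axis=0) > 0).all():
            continue
        if full_rank and np.linalg.matrix_rank(dense) < size * size:
            continue
        mu_true = rng.uniform(0.005, 0.04, (size, size))
        sino = forward_project(ImageGrid(mu_true, 1.0, "MU"), matrix)
        return matrix, sino, dense, mu_true
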