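"""Synthetic 2-D abdominal phantoms with labelled organ regions.

The phantom is a layered list of ellipses on a square field of view.
Later ellipses overwrite earlier ones where they overlap, the same
convention the Shepp-Logan family of phantoms uses for nested anatomy.

Coordinate convention (shared by every module in this package):
physical origin at the grid centre, x to the right, y up, units mm;
array element (0, 0) is the top-left pixel; ``pixel_spacing =
field_of_view / size``; a pixel belongs to the last ellipse whose
interior contains its centre (no anti-aliasing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "ImageGrid",
    "default_abdomen_spec",
    "render_phantom",
    "region_mask",
]

#: Hounsfield value of air; pixels covered by no ellipse default to this.
HU_AIR = -1000.0


@dataclass(frozen=True)
class Ellipse:
    """One elliptical region of uniform Hounsfield value.

    Parameters
    ----------
    center_x, center_y : float
        Centre in physical coordinates (mm), origin at the grid centre.
    semi_axis_a, semi_axis_b : float
        Semi-axes (mm) along the ellipse's own x/y axes before rotation.
    rotation : float
        Counter-clockwise rotation in degrees, in [0, 360).
    hu_value : float
        Hounsfield value assigned to the interior.
    label : str
        Free-text region name ("liver", "fat", ...).
    """

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float = 0.0
    hu_value: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not 0.0 <= self.rotation < 360.0:
            raise ValueError("rotation must lie in [0, 360) degrees")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean interior test for physical coordinates (vectorised)."""
        phi = math.radians(self.rotation)
        dx = np.asarray(x) - self.center_x
        dy = np.asarray(y) - self.center_y
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        return (u / self.semi_axis_a) ** 2 + (v / self.semi_axis_b) ** 2 <= 1.0

    @property
    def area(self) -> float:
        """Analytic area in mm^2."""
        return math.pi * self.semi_axis_a * self.semi_axis_b


@dataclass(frozen=True)
class PhantomSpec:
    """Ordered ellipse list plus field-of-view; later entries overwrite earlier."""

    ellipses: tuple[Ellipse, ...] = ()
    field_of_view: float = 220.0
    background_hu: float = HU_AIR

    def __post_init__(self) -> None:
        if self.field_of_view <= 0:
            raise ValueError("field_of_view must be positive")
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        half = self.field_of_view / 2.0
        for e in self.ellipses:
            reach = max(e.semi_axis_a, e.semi_axis_b)
            if (abs(e.center_x) + reach > half) or (abs(e.center_y) + reach > half):
                raise ValueError(
                    f"ellipse {e.label!r} does not fit inside the "
                    f"{self.field_of_view} mm field of view"
                )

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.ellipses]

    def with_seed_noise(self) -> "PhantomSpec":  # pragma: no cover - convenience
        return self


@dataclass
class ImageGrid:
    """Square 2-D image with geometry metadata.

    ``value_kind`` is ``"HU"`` (Hounsfield units) or ``"MU"`` (linear
    attenuation, mm^-1) and fixes the units of every pixel.
    """

    pixels: np.ndarray
    pixel_spacing: float
    value_kind: str = "HU"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.value_kind not in ("HU", "MU"):
            raise ValueError("value_kind must be 'HU' or 'MU'")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def field_of_view(self) -> float:
        return self.size * self.pixel_spacing

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.pixels.copy(), self.pixel_spacing, self.value_kind)


def pixel_centers(size: int, pixel_spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical (x, y) coordinates of every pixel centre.

    Returns two ``size x size`` arrays; row 0 is the top of the image
    (largest y), column 0 the left (smallest x).
    """
    half = size * pixel_spacing / 2.0
    coords = (np.arange(size) + 0.5) * pixel_spacing
    x = coords - half
    y = half - coords
    return np.meshgrid(x, y)  # xg varies along columns, yg along rows


def default_abdomen_spec() -> PhantomSpec:
    """Abdominal slice stand-in: fat ring, soft-tissue body, liver, gallbladder.

    Region Hounsfield values are chosen so that organ ROI means land near
    typical portal-phase abdominal readings (liver about 77 HU, gallbladder
    bile about 55 HU, subcutaneous fat about -90 HU, soft tissue about
    40 HU) inside the default 220 mm field of view.
    """
    ellipses = (
        Ellipse(0.0, 0.0, 105.0, 85.0, 0.0, -90.0, "fat"),
        Ellipse(0.0, 0.0, 92.0, 72.0, 0.0, 40.0, "body"),
        Ellipse(-38.0, 14.0, 44.0, 30.0, 15.0, 77.0, "liver"),
        Ellipse(2.0, -30.0, 17.0, 12.0, 0.0, 55.0, "gallbladder"),
    )
    return PhantomSpec(ellipses=ellipses, field_of_view=220.0, background_hu=HU_AIR)


def render_phantom(spec: PhantomSpec, size: int = 512) -> ImageGrid:
    """Rasterise a phantom spec onto a ``size x size`` HU grid.

    Each pixel takes the ``hu_value`` of the last ellipse whose interior
    contains the pixel centre, else ``spec.background_hu``. Deterministic:
    identical inputs give bit-identical output.
    """
    if size < 8:
        raise ValueError("size must be at least 8 pixels")
    spacing = spec.field_of_view / size
    xg, yg = pixel_centers(size, spacing)
    img = np.full((size, size), spec.background_hu, dtype=float)
    for e in spec.ellipses:
        img[e.contains(xg, yg)] = e.hu_value
    return ImageGrid(img, spacing, "HU")


def region_mask(spec: PhantomSpec, label: str, size: int = 512) -> np.ndarray:
    """Boolean mask of the pixels that ``render_phantom`` assigns to ``label``.

    Honors the overwrite order: pixels of the labelled ellipse covered by a
    later ellipse are excluded. Raises ``KeyError`` for unknown labels.
    """
    if label not in spec.labels:
        raise KeyError(f"no region labelled {label!r} in phantom spec")
    if size < 8:
        raise ValueError("size must be at least 8 pixels")
    spacing = spec.field_of_view / size
    xg, yg = pixel_centers(size, spacing)
    owner = np.full((size, size), -1, dtype=int)
    for i, e in enumerate(spec.ellipses):
        owner[e.contains(xg, yg)] = i
    mask = np.zeros((size, size), dtype=bool)
    for i, e in enumerate(spec.ellipses):
        if e.label == label:
            mask |= owner == i
    return mask
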