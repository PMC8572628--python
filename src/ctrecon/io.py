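"""File formats and run configuration.

Images travel as 16-bit TIFF (HU offset by +1024, clamped to [0, 65535]),
as a raw float32 container with a plain-text sidecar header, or read-only
as DICOM (rescale slope/intercept applied). Sinograms use the same
raw + header container. Phantom specs and run configurations round-trip
through YAML. Every artifact the pipeline writes carries the config hash
and seed in its header or sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .asir import IterConfig
from .fbp import FBPConfig
from .phantom import Ellipse, ImageGrid, PhantomSpec, default_abdomen_spec
from .projection import MU_WATER, NoiseModel, ScanGeometry, Sinogram

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "config_hash",
    "save_spec",
    "load_spec",
    "read_image",
    "write_image",
    "read_sinogram",
    "write_sinogram",
]


class ConfigError(ValueError):
    """A config file failed validation; the message names the key path."""


# ---------------------------------------------------------------------------
# phantom spec <-> YAML

def save_spec(spec: PhantomSpec, path: str | Path) -> None:
    doc = {
        "field_of_view": spec.field_of_view,
        "background_hu": spec.background_hu,
        "ellipses": [
            {
                "center_x": e.center_x,
                "center_y": e.center_y,
                "semi_axis_a": e.semi_axis_a,
                "semi_axis_b": e.semi_axis_b,
                "rotation": e.rotation,
                "hu_value": e.hu_value,
                "label": e.label,
            }
            for e in spec.ellipses
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_spec(path: str | Path) -> PhantomSpec:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: phantom spec must be a mapping")
    try:
        ellipses = tuple(Ellipse(**e) for e in doc.get("ellipses", []))
        return PhantomSpec(
            ellipses=ellipses,
            field_of_view=float(doc.get("field_of_view", 220.0)),
            background_hu=float(doc.get("background_hu", -1000.0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# raw float container with sidecar text header

def _write_raw(values: np.ndarray, path: Path, header: dict) -> None:
    values.astype("<f4").tofile(path)
    lines = [f"{k}: {v}" for k, v in header.items()]
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(lines) + "\n")


def _read_header(path: Path) -> dict:
    header = {}
    for line in path.read_text().splitlines():
        if line.strip():
            key, _, value = line.partition(":")
            header[key.strip()] = value.strip()
    return header


def write_image(image: ImageGrid, path: str | Path, provenance: dict | None = None) -> None:
    """Write an image as raw float32 + sidecar (``.raw``) or 16-bit TIFF.

    TIFF output stores HU + 1024 clamped to the uint16 range, so values
    round-trip only to the nearest integer HU; the raw container is exact
    to float32.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        if image.value_kind != "HU":
            raise ValueError("TIFF export expects an HU image")
        stored = np.clip(np.round(image.pixels + 1024.0), 0, 65535).astype(np.uint16)
        desc = {"pixel_spacing_mm": image.pixel_spacing, "hu_offset": 1024}
        desc.update(provenance or {})
        tifffile.imwrite(path, stored, description=json.dumps(desc))
    elif path.suffix.lower() == ".raw":
        header = {
            "type": "image",
            "size": image.size,
            "pixel_spacing_mm": image.pixel_spacing,
            "value_kind": image.value_kind,
            "dtype": "float32",
        }
        header.update(provenance or {})
        _write_raw(image.pixels, path, header)
    else:
        raise IOError(f"unsupported image format {path.suffix!r} (use .tiff or .raw)")


def read_image(path: str | Path) -> ImageGrid:
    """Read a DICOM, TIFF or raw-container image as an HU (or stored-kind) grid."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path)
    if suffix == ".raw":
        header = _read_header(path.with_suffix(path.suffix + ".hdr"))
        size = int(header["size"])
        pixels = np.fromfile(path, dtype="<f4").reshape(size, size).astype(float)
        return ImageGrid(pixels, float(header["pixel_spacing_mm"]), header["value_kind"])
    raise IOError(f"unsupported image format {path.suffix!r}")


def _read_tiff(path: Path) -> ImageGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stored = tif.asarray().astype(float)
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    spacing = float(meta.get("pixel_spacing_mm", 1.0))
    offset = float(meta.get("hu_offset", 1024))
    return ImageGrid(stored - offset, spacing, "HU")


def _read_dicom(path: Path) -> ImageGrid:
    import pydicom

    ds = pydicom.dcmread(path)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(float) * slope + intercept
    spacing_attr = getattr(ds, "PixelSpacing", None)
    if spacing_attr is None:
        raise IOError(f"{path}: DICOM file lacks PixelSpacing")
    return ImageGrid(pixels, float(spacing_attr[0]), "HU")


def write_sinogram(sinogram: Sinogram, path: str | Path, provenance: dict | None = None) -> None:
    """Raw float32 sinogram plus sidecar geometry header."""
    path = Path(path)
    geom = sinogram.geometry
    header = {
        "type": "sinogram",
        "n_angles": geom.n_angles,
        "n_detectors": geom.n_detectors,
        "detector_spacing_mm": geom.detector_spacing,
        "field_of_view_mm": geom.field_of_view,
        "dtype": "float32",
    }
    header.update(provenance or {})
    _write_raw(sinogram.values, path, header)


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    header = _read_header(path.with_suffix(path.suffix + ".hdr"))
    geom = ScanGeometry(
        n_angles=int(header["n_angles"]),
        n_detectors=int(header["n_detectors"]),
        detector_spacing=float(header["detector_spacing_mm"]),
        field_of_view=float(header["field_of_view_mm"]),
    )
    values = np.fromfile(path, dtype="<f4").reshape(geom.n_angles, geom.n_detectors)
    return Sinogram(values.astype(float), geom)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything one end-to-end comparison run needs.

    Defaults encode the simulated acquisition: 220 mm field of view,
    256 x 256 grid, 180 parallel-beam views, noise index 24, Hann-filtered
    back projection, and a 20-iteration relaxation-1 algebraic loop started
    from a zero image. Tube settings (kV, mAs) are carried as metadata only.
    """

    phantom: PhantomSpec = field(default_factory=default_abdomen_spec)
    size: int = 256
    n_angles: int = 180
    n_detectors: int | None = None
    detector_spacing: float | None = None
    noise_index: float = 24.0
    incident_counts: float | None = None
    seed: int = 0
    fbp: FBPConfig | None = None
    iter: IterConfig = field(
        default_factory=lambda: IterConfig(max_iterations=20, init_mode="zero")
    )
    rois: tuple[str, ...] = ("liver", "gallbladder", "fat", "body")
    repeats: int = 3
    jitter: int = 2
    roi_erode: int = 3
    mu_water: float = MU_WATER
    kv: float = 120.0
    mas: float = 150.0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.fbp is None:
            self.fbp = FBPConfig(
                filter_window="hann",
                output_size=self.size,
                pixel_spacing=self.phantom.field_of_view / self.size,
            )

    @property
    def geometry(self) -> ScanGeometry:
        fov = self.phantom.field_of_view
        if self.n_detectors is None or self.detector_spacing is None:
            geom = ScanGeometry.for_image(self.size, fov, self.n_angles)
            n_det = self.n_detectors or geom.n_detectors
            spacing = self.detector_spacing or geom.detector_spacing
            return ScanGeometry(self.n_angles, n_det, spacing, fov)
        return ScanGeometry(self.n_angles, self.n_detectors, self.detector_spacing, fov)

    @property
    def pixel_spacing(self) -> float:
        return self.phantom.field_of_view / self.size


_SCHEMA = {
    "phantom": ("default", dict, str),
    "size": int,
    "n_angles": int,
    "n_detectors": (int, type(None)),
    "detector_spacing": (float, int, type(None)),
    "noise": {"noise_index": (float, int), "incident_counts": (float, int, type(None)),
              "seed": int},
    "fbp": {"filter_window": str},
    "iter": {"max_iterations": int, "tolerance": (float, int),
             "relaxation": (float, int), "blend_fraction": (float, int),
             "init_mode": str, "uniform_value": (float, int)},
    "rois": list,
    "repeats": int,
    "jitter": int,
    "roi_erode": int,
    "mu_water": (float, int),
    "kv": (float, int),
    "mas": (float, int),
    "output_dir": (str, type(None)),
}


def _check_keys(doc: dict, schema: dict, prefix: str = "") -> None:
    for key, value in doc.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {prefix + key!r}")
        rule = schema[key]
        if isinstance(rule, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {prefix}{key!r} must be a mapping")
            _check_keys(value, rule, prefix=f"{prefix}{key}.")


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; missing keys take defaults.

    An empty (or absent) file yields the default configuration. Unknown
    keys are rejected with the offending key path named. ``overrides``
    (e.g. from CLI flags) are applied on top of the file.
    """
    doc: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        doc = loaded
    for key, value in (overrides or {}).items():
        section, _, sub = key.partition(".")
        if sub:
            doc.setdefault(section, {})[sub] = value
        else:
            doc[key] = value
    _check_keys(doc, _SCHEMA)

    phantom = doc.get("phantom", "default")
    if phantom == "default":
        spec = default_abdomen_spec()
    elif isinstance(phantom, str):
        spec = load_spec(phantom)
    else:
        try:
            spec = PhantomSpec(
                ellipses=tuple(Ellipse(**e) for e in phantom.get("ellipses", [])),
                field_of_view=float(phantom.get("field_of_view", 220.0)),
                background_hu=float(phantom.get("background_hu", -1000.0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"phantom: {exc}") from exc

    size = int(doc.get("size", 256))
    noise = doc.get("noise", {})
    iter_doc = doc.get("iter", {})
    fbp_doc = doc.get("fbp", {})
    try:
        iter_cfg = IterConfig(
            max_iterations=int(iter_doc.get("max_iterations", 20)),
            tolerance=float(iter_doc.get("tolerance", 1e-4)),
            relaxation=float(iter_doc.get("relaxation", 1.0)),
            blend_fraction=float(iter_doc.get("blend_fraction", 1.0)),
            init_mode=str(iter_doc.get("init_mode", "zero")),
            uniform_value=float(iter_doc.get("uniform_value", 0.0)),
        )
        fbp_cfg = FBPConfig(
            filter_window=str(fbp_doc.get("filter_window", "hann")),
            output_size=size,
            pixel_spacing=spec.field_of_view / size,
        )
        config = RunConfig(
            phantom=spec,
            size=size,
            n_angles=int(doc.get("n_angles", 180)),
            n_detectors=doc.get("n_detectors"),
            detector_spacing=doc.get("detector_spacing"),
            noise_index=float(noise.get("noise_index", 24.0)),
            incident_counts=noise.get("incident_counts"),
            seed=int(noise.get("seed", 0)),
            fbp=fbp_cfg,
            iter=iter_cfg,
            rois=tuple(doc.get("rois", ("liver", "gallbladder", "fat", "body"))),
            repeats=int(doc.get("repeats", 3)),
            jitter=int(doc.get("jitter", 2)),
            roi_erode=int(doc.get("roi_erode", 3)),
            mu_water=float(doc.get("mu_water", MU_WATER)),
            kv=float(doc.get("kv", 120.0)),
            mas=float(doc.get("mas", 150.0)),
            output_dir=doc.get("output_dir"),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    if config.noise_index < 0:
        raise ConfigError("noise.noise_index must be >= 0")
    if config.size < 8:
        raise ConfigError("size must be >= 8")
    config.geometry  # validates detector coverage
    return config


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a run configuration, for artifact provenance."""
    doc = asdict(config)
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
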