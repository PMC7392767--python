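"""Dataset manifest and TIFF I/O.

A multi-view acquisition is stored as one multi-page grayscale TIFF per view
(page axis = z) plus a JSON manifest recording the view angles and the
optical/acquisition metadata.  Reconstructed volumes are written as 32-bit
float multi-page TIFF (page axis = y) with the pixel size in the TIFF
resolution tags and a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile

from .params import OpticalParams, AcquisitionGeometry, ValidationError
from .simulate import ViewStack, MultiViewDataset
from .recon import ReconVolume

__all__ = ["DatasetManifest", "ManifestError", "FormatError",
           "load_manifest", "save_manifest", "read_view_stack",
           "write_view_stack", "load_dataset", "save_dataset", "write_volume",
           "read_volume"]

MANIFEST_VERSION = "1"


class ManifestError(ValidationError):
    """Manifest fails schema validation; message lists all violations."""


class FormatError(ValueError):
    """An image file is unreadable or has an unsupported layout."""


@dataclass
class DatasetManifest:
    """Schema of the per-dataset JSON manifest."""

    views: list[dict]  # each {"path": str, "angle_deg": float}
    axial_step_um: float
    pixel_size_um: float
    wavelength_um: float
    na_det: float
    na_ill: float
    refractive_index: float = 1.0
    background_level: float | None = None
    seed: int | None = None
    version: str = MANIFEST_VERSION
    root: Path | None = field(default=None, repr=False)  # set on load

    def optical_params(self) -> OpticalParams:
        return OpticalParams(wavelength=self.wavelength_um, na_det=self.na_det,
                             na_ill=self.na_ill,
                             refractive_index=self.refractive_index,
                             pixel_size=self.pixel_size_um)


def _validate_manifest(m: DatasetManifest, check_files: bool = True) -> None:
    errors = []
    if not m.views:
        errors.append("manifest lists no views")
    angles = [v.get("angle_deg") for v in m.views]
    seen: dict[float, int] = {}
    for i, a in enumerate(angles):
        if a is None:
            errors.append(f"view {i} has no angle_deg")
            continue
        key = round(float(a) % 360.0, 9)
        if key in seen:
            errors.append(
                f"duplicate angle {a}° in view entries {seen[key]} and {i}")
        seen[key] = i
    for name in ("axial_step_um", "pixel_size_um", "wavelength_um",
                 "na_det", "na_ill", "refractive_index"):
        value = getattr(m, name)
        if value is None or not value > 0:
            errors.append(f"{name} must be a positive number, got {value}")
    if check_files and m.root is not None:
        for i, v in enumerate(m.views):
            path = m.root / v.get("path", "")
            if not path.is_file():
                errors.append(f"view {i} file not found: {path}")
    if errors:
        raise ManifestError("invalid manifest: " + "; ".join(errors))


def load_manifest(path) -> DatasetManifest:
    """Load and validate a manifest; relative view paths resolve against the
    manifest's directory."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    known = {f for f in DatasetManifest.__dataclass_fields__ if f != "root"}
    manifest = DatasetManifest(**{k: v for k, v in raw.items() if k in known},
                               root=path.parent)
    _validate_manifest(manifest)
    return manifest


def save_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    manifest.root = path.parent
    _validate_manifest(manifest, check_files=False)
    payload = {k: v for k, v in asdict(manifest).items() if k != "root"}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


_SUPPORTED_DTYPES = ("uint8", "uint16", "int16", "float32", "float64")


def read_view_stack(path, manifest: DatasetManifest | None = None,
                    angle: float = 0.0) -> ViewStack:
    """Read one multi-page grayscale TIFF as a (z, y, x) view stack.

    Integer data are converted to float64 without rescaling.  Metadata
    (angle, steps) comes from the manifest when given.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            for i, page in enumerate(tf.pages):
                if page.samplesperpixel != 1:
                    raise FormatError(
                        f"{path} page {i}: {page.samplesperpixel} samples per "
                        f"pixel (RGB/multi-sample TIFFs are unsupported)")
            data = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt files must not crash callers
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale z stack, got shape {data.shape} "
            f"(RGB/multi-sample TIFFs are unsupported)")
    if str(data.dtype) not in _SUPPORTED_DTYPES:
        raise FormatError(f"{path}: unsupported sample format {data.dtype}")
    data = np.ascontiguousarray(data, dtype=np.float64) \
        if not np.issubdtype(data.dtype, np.floating) else np.asarray(data)
    if manifest is not None:
        return ViewStack(intensity=np.asarray(data, dtype=float),
                         angle=float(angle) % 360.0,
                         axial_step=manifest.axial_step_um,
                         pixel_size=manifest.pixel_size_um,
                         background_level=manifest.background_level or 1.0)
    return ViewStack(intensity=np.asarray(data, dtype=float),
                     angle=float(angle) % 360.0, axial_step=1.0,
                     pixel_size=1.0)


def write_view_stack(stack: ViewStack, path) -> None:
    """Write a view stack as 32-bit float multi-page TIFF (page axis = z)."""
    _write_tiff(np.asarray(stack.intensity, dtype=np.float32), path,
                stack.pixel_size)


def _write_tiff(data: np.ndarray, path, pixel_size_um: float) -> None:
    # TIFF resolution tags are pixels per unit; use pixels/cm
    per_cm = 1e4 / pixel_size_um
    tifffile.imwrite(path, data, photometric="minisblack",
                     resolution=(per_cm, per_cm),
                     resolutionunit="CENTIMETER")


def load_dataset(manifest: DatasetManifest) -> MultiViewDataset:
    """Materialise the full multi-view dataset a manifest describes."""
    if manifest.root is None:
        raise ManifestError("manifest has no root directory; load it from disk")
    views = []
    shape = None
    for entry in manifest.views:
        stack = read_view_stack(manifest.root / entry["path"], manifest,
                                angle=entry["angle_deg"])
        if shape is None:
            shape = stack.intensity.shape
        elif stack.intensity.shape != shape:
            raise ManifestError(
                f"view {entry['path']} shape {stack.intensity.shape} differs "
                f"from {shape}")
        views.append(stack)
    angles = tuple(float(v["angle_deg"]) % 360.0 for v in manifest.views)
    geometry = AcquisitionGeometry(angles=angles,
                                   axial_step=manifest.axial_step_um,
                                   num_z_steps=views[0].intensity.shape[0])
    return MultiViewDataset(views=views, params=manifest.optical_params(),
                            geometry=geometry)


def save_dataset(dataset: MultiViewDataset, out_dir, seed: int | None = None
                 ) -> Path:
    """Write one TIFF per view plus the manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, view in enumerate(dataset.views):
        name = f"view_{i:03d}_angle_{view.angle:07.3f}.tif"
        write_view_stack(view, out_dir / name)
        entries.append({"path": name, "angle_deg": view.angle})
    p = dataset.params
    manifest = DatasetManifest(
        views=entries, axial_step_um=dataset.geometry.axial_step,
        pixel_size_um=p.pixel_size, wavelength_um=p.wavelength,
        na_det=p.na_det, na_ill=p.na_ill,
        refractive_index=p.refractive_index,
        background_level=dataset.views[0].background_level, seed=seed)
    path = out_dir / "manifest.json"
    save_manifest(manifest, path)
    return path


def write_volume(volume: ReconVolume, path) -> None:
    """Write a reconstructed volume as float32 TIFF (page axis = y) with a
    JSON provenance sidecar next to it."""
    path = Path(path)
    data = np.asarray(volume.values, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValidationError("volume contains non-finite values")
    _write_tiff(data, path, volume.voxel_size[-1])
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"voxel_size_um": list(volume.voxel_size),
                   "provenance": volume.provenance}, fh, indent=2, default=str)


def read_volume(path) -> ReconVolume:
    """Read back a volume written by :func:`write_volume`."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".json")
    voxel = (1.0, 1.0, 1.0)
    prov: dict = {}
    if sidecar.is_file():
        with open(sidecar) as fh:
            meta = json.load(fh)
        voxel = tuple(meta.get("voxel_size_um", voxel))
        prov = meta.get("provenance", {})
    return ReconVolume(values=np.asarray(data), voxel_size=voxel,
                       provenance=prov)
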