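"""NIfTI I/O and the core in-memory containers.

A :class:`Volume` is a 3D scalar field of SUV values (g/mL) together with its
voxel spacing in mm; a :class:`GatedStudy` bundles the g respiratory gates of
one acquisition with the ungated reference image. All downstream stages
(filtering, optimization, metrics, network training) operate on these
containers.

Only single-file NIfTI-1 (.nii / .nii.gz) with axis-aligned orientation is
supported; DICOM ingestion and oblique affines are out of scope. Voxel index
``v`` maps to physical position ``origin + v * spacing`` (mm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path


import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError, GeometryError, ValidationError

__all__ = [
    "Volume",
    "RoiMask",
    "RoiSet",
    "GatedStudy",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_study",
    "save_study",
]


@dataclass
class Volume:
    """A 3D PET image in SUV units with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValidationError(f"degenerate shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.isfinite(self.data).all():
            raise ValidationError("volume contains non-finite values")
        if (self.data < 0).any():
            warnings.warn("volume contains negative SUV values", stacklevel=3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid with replaced intensities."""
        return Volume(data, self.spacing, self.origin)

    def congruent_with(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class RoiMask:
    """Binary ROI congruent with an associated :class:`Volume`.

    ``role`` is ``"liver"`` (noise-assessment region) or ``"lesion"``
    (focal-uptake region).
    """

    mask: np.ndarray
    role: str
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise FormatError(f"expected 3D mask, got ndim={self.mask.ndim}")
        if self.role not in ("liver", "lesion"):
            raise ValidationError(f"role must be 'liver' or 'lesion', got {self.role!r}")
        if not self.mask.any():
            raise ValidationError(f"mask {self.label!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiSet:
    """One liver mask plus the lesion masks of a study."""

    liver: RoiMask
    lesions: list[RoiMask]

    def __post_init__(self) -> None:
        if self.liver.role != "liver":
            raise ValidationError("RoiSet.liver must have role 'liver'")
        for m in self.lesions:
            if m.role != "lesion":
                raise ValidationError("RoiSet.lesions entries must have role 'lesion'")


@dataclass
class GatedStudy:
    """Ordered respiratory gates plus the ungated reference image."""

    gates: list[Volume]
    ungated: Volume
    tracer: str = ""

    def __post_init__(self) -> None:
        if not self.gates:
            raise ValidationError("study needs at least one gate")
        for i, g in enumerate(self.gates):
            if not g.congruent_with(self.ungated):
                raise GeometryError(f"gate {i} geometry differs from ungated volume")

    @property
    def gate_count(self) -> int:
        return len(self.gates)


def _check_axis_aligned(affine: np.ndarray) -> None:
    rot = affine[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > 1e-4 * max(1.0, np.abs(rot).max()):
        raise GeometryError("oblique (non-axis-aligned) orientation is not supported")


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 volume; spacing is taken from the header (mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D scalar payload, got shape {data.shape}")
    _check_axis_aligned(img.affine)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(np.asarray(data, dtype=np.float64), spacing, origin)


def _affine(vol: Volume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as single-file NIfTI-1; round-trips losslessly."""
    if not np.isfinite(vol.data).all():
        raise ValidationError("refusing to write non-finite volume")
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, ref: Volume, role: str = "lesion", label: str = "") -> RoiMask:
    """Read a mask file (nonzero voxels -> True) on the grid of ``ref``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask payload, got shape {data.shape}")
    if data.shape != ref.shape:
        raise GeometryError(f"{path}: mask shape {data.shape} != reference {ref.shape}")
    return RoiMask(data != 0, role=role, label=label or path.stem)


def write_mask(mask: RoiMask, ref: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(ref))
    img.header.set_zooms(ref.spacing)
    nib.save(img, str(path))


def load_study(manifest_path: str | Path) -> tuple[GatedStudy, RoiSet, dict]:
    """Load a study from a YAML/JSON manifest.

    The manifest lists ``gates`` (ordered paths), ``ungated``, ``liver_mask``
    and ``lesion_masks`` paths, relative to the manifest's directory unless
    absolute. Returns the study, its ROI set, and the raw manifest dict
    (which may carry provenance, e.g. an embedded phantom configuration).
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest = json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    base = manifest_path.parent

    def _p(rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else base / p

    gates = [read_volume(_p(p)) for p in manifest["gates"]]
    ungated = read_volume(_p(manifest["ungated"]))
    study = GatedStudy(gates, ungated, tracer=manifest.get("tracer", ""))
    liver = read_mask(_p(manifest["liver_mask"]), ungated, role="liver", label="liver")
    lesions = [
        read_mask(_p(p), ungated, role="lesion", label=f"lesion{j + 1}")
        for j, p in enumerate(manifest.get("lesion_masks", []))
    ]
    return study, RoiSet(liver, lesions), manifest


def save_study(
    study: GatedStudy,
    rois: RoiSet,
    out_dir: str | Path,
    extra: dict | None = None,
) -> Path:
    """Write gates, ungated image and masks as NIfTI plus a YAML manifest.

    ``extra`` entries (e.g. phantom provenance) are embedded in the manifest.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"gates": [], "tracer": study.tracer}
    for i, gate in enumerate(study.gates):
        name = f"gate_{i:02d}.nii.gz"
        write_volume(gate, out_dir / name)
        manifest["gates"].append(name)
    write_volume(study.ungated, out_dir / "ungated.nii.gz")
    manifest["ungated"] = "ungated.nii.gz"
    write_mask(rois.liver, study.ungated, out_dir / "liver_mask.nii.gz")
    manifest["liver_mask"] = "liver_mask.nii.gz"
    manifest["lesion_masks"] = []
    for j, lesion in enumerate(rois.lesions):
        name = f"lesion_mask_{j + 1}.nii.gz"
        write_mask(lesion, study.ungated, out_dir / name)
        manifest["lesion_masks"].append(name)
    if extra:
        manifest.update(extra)
    manifest_path = out_dir / "study.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
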