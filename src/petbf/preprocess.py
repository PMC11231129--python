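"""Normalization, patch extraction and run-time augmentation for training.

Training samples are co-located 32^3 patches cut from an
(unfiltered, filtered) volume pair after a shared affine map to [0, 1].
The map is computed from the joint min/max of the pair so that a single
record inverts both volumes — per-volume scaling would make the residual
learning target inconsistent between input and output.

Patches are extracted on a regular lattice whose stride guarantees at
least 25% overlap between adjacent patches, with the last patch snapped to
the volume boundary so every voxel is covered.

Augmentation (drawn fresh at run time) consists of independent 50% flips
per axis and a gamma correction v -> v^gamma applied identically to input
and target, with gamma = (1 + |G|)^sign(G) for G ~ N(0, 0.5^2) — a
multiplicatively symmetric distribution around gamma = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError
from .volume_io import Volume

__all__ = [
    "NormRecord",
    "PatchPair",
    "normalize_pair",
    "normalize_volume",
    "extract_patches",
    "make_patch_pairs",
    "gamma_value",
    "augment_pair",
]

PATCH_SIZE = 32
MIN_OVERLAP_FRAC = 0.25


@dataclass(frozen=True)
class NormRecord:
    """Affine intensity map: ``offset`` -> 0.0 and ``scale`` -> 1.0 (SUV)."""

    scale: float
    offset: float

    def __post_init__(self) -> None:
        if not self.scale > self.offset:
            raise ValidationError(f"degenerate normalization: scale={self.scale} offset={self.offset}")

    def apply(self, data: np.ndarray) -> np.ndarray:
        return (data - self.offset) / (self.scale - self.offset)

    def invert(self, data: np.ndarray) -> np.ndarray:
        return data * (self.scale - self.offset) + self.offset


@dataclass
class PatchPair:
    """Co-located normalized input/target patches and their origin corner."""

    input_patch: np.ndarray
    target_patch: np.ndarray
    corner: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.input_patch.shape != self.target_patch.shape:
            raise GeometryError("input and target patches must share shape")


def normalize_volume(vol: Volume) -> tuple[Volume, NormRecord]:
    """Map one volume to [0, 1] by its own min/max."""
    lo, hi = float(vol.data.min()), float(vol.data.max())
    rec = NormRecord(scale=hi, offset=lo)
    return vol.with_data(rec.apply(vol.data)), rec


def normalize_pair(unfiltered: Volume, filtered: Volume) -> tuple[Volume, Volume, NormRecord]:
    """Map a volume pair into [0, 1] with a single shared affine record."""
    if not unfiltered.congruent_with(filtered):
        raise GeometryError("pair volumes are not congruent")
    lo = min(float(unfiltered.data.min()), float(filtered.data.min()))
    hi = max(float(unfiltered.data.max()), float(filtered.data.max()))
    rec = NormRecord(scale=hi, offset=lo)
    return (
        unfiltered.with_data(rec.apply(unfiltered.data)),
        filtered.with_data(rec.apply(filtered.data)),
        rec,
    )


def _axis_corners(length: int, size: int, stride: int) -> list[int]:
    corners = list(range(0, length - size + 1, stride))
    if corners[-1] != length - size:
        corners.append(length - size)
    return corners


def patch_corners(
    shape: tuple[int, int, int],
    size: int = PATCH_SIZE,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
) -> list[tuple[int, int, int]]:
    """Corner lattice covering the volume with >= min_overlap_frac overlap.

    Per axis the stride is ``floor(size * (1 - min_overlap_frac))`` (24 for
    the defaults) and the final corner abuts the boundary.
    """
    if any(n < size for n in shape):
        raise GeometryError(f"volume shape {shape} smaller than patch size {size}")
    stride = int(np.floor(size * (1.0 - min_overlap_frac)))
    axes = [_axis_corners(n, size, stride) for n in shape]
    return [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]]


def extract_patches(
    vol: Volume,
    size: int = PATCH_SIZE,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
) -> list[tuple[np.ndarray, tuple[int, int, int]]]:
    """Cut the covering patch lattice out of one volume."""
    out = []
    for c in patch_corners(vol.shape, size, min_overlap_frac):
        sl = tuple(slice(a, a + size) for a in c)
        out.append((vol.data[sl].copy(), c))
    return out


def make_patch_pairs(
    unfiltered: Volume,
    filtered: Volume,
    size: int = PATCH_SIZE,
    min_overlap_frac: float = MIN_OVERLAP_FRAC,
) -> tuple[list[PatchPair], NormRecord]:
    """Normalize a volume pair jointly and cut co-located patch pairs."""
    u, f, rec = normalize_pair(unfiltered, filtered)
    pairs = [
        PatchPair(pu, pf, c)
        for (pu, c), (pf, _) in zip(
            extract_patches(u, size, min_overlap_frac),
            extract_patches(f, size, min_overlap_frac),
        )
    ]
    return pairs, rec


def gamma_value(g: float) -> float:
    """Gamma exponent (1 + |G|)^sign(G); sign(0) = 0 gives gamma = 1 exactly."""
    g = float(g)
    return (1.0 + abs(g)) ** float(np.sign(g))


def augment_pair(pair: PatchPair, seed: int | np.random.Generator) -> PatchPair:
    """Random flips plus shared gamma correction of both patches.

    Each axis is flipped independently with probability 1/2; one gamma is
    drawn per pair (G ~ N(0, 0.5^2)) and v -> v^gamma applied to input and
    target identically, so an identical pair stays identical and [0, 1] is
    preserved (0 and 1 are fixed points of the power map).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flips = rng.random(3) < 0.5
    gamma = gamma_value(rng.normal(0.0, 0.5))
    axes = tuple(int(a) for a in np.nonzero(flips)[0])

    def _t(p: np.ndarray) -> np.ndarray:
        q = np.flip(p, axis=axes) if axes else p
        return np.clip(q, 0.0, None) ** gamma

    return PatchPair(_t(pair.input_patch), _t(pair.target_patch), pair.corner)
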