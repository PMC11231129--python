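"""Quantitative evaluation of filtering: SUVmax, liver noise level, and
pairwise absolute / symmetric fractional differences.

Noise level is the coefficient of variation over a homogeneous liver ROI,
``100 * sd / mean`` (percent); SUVmax is the maximum voxel value in a focal
uptake ROI. Differences between two image types A and B are reported as the
absolute difference ``Delta = a - b`` and the symmetric fractional
difference ``delta = (a - b) / [(a + b)/2] * 100%``, which is bounded in
[-200, 200]% and antisymmetric in its arguments. The focal-uptake-to-liver
ratio FLR (lesion SUVmax over liver SUVmean) is the contrast covariate used
to stratify lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MetricUndefinedError, ValidationError
from .volume_io import RoiMask, RoiSet, Volume

__all__ = [
    "suv_max",
    "suv_mean",
    "noise_level",
    "delta_abs",
    "delta_frac",
    "flr",
    "MetricsReport",
    "evaluate_images",
]


def _check(vol: Volume, roi: RoiMask) -> np.ndarray:
    if roi.mask.shape != vol.shape:
        raise ValidationError(f"ROI shape {roi.mask.shape} != volume shape {vol.shape}")
    return vol.data[roi.mask]


def suv_max(vol: Volume, roi: RoiMask) -> float:
    """Maximum SUV over the masked voxels (g/mL)."""
    return float(_check(vol, roi).max())


def suv_mean(vol: Volume, roi: RoiMask) -> float:
    """Mean SUV over the masked voxels (g/mL)."""
    return float(_check(vol, roi).mean())


def noise_level(vol: Volume, liver: RoiMask) -> float:
    """Liver coefficient of variation, percent: 100 * sd / mean.

    Sample (n-1) standard deviation; for liver ROIs of thousands of voxels
    the convention is immaterial but it is fixed for reproducibility.
    """
    vals = _check(vol, liver)
    if vals.size < 2:
        raise MetricUndefinedError("noise level needs >= 2 liver voxels")
    mean = float(vals.mean())
    if mean <= 0:
        raise MetricUndefinedError(f"liver mean must be > 0 for CV, got {mean}")
    return 100.0 * float(vals.std(ddof=1)) / mean


def delta_abs(a: float, b: float) -> float:
    """Absolute difference a - b (same units as the inputs)."""
    return float(a) - float(b)


def delta_frac(a: float, b: float) -> float:
    """Symmetric fractional difference, percent: (a-b) / [(a+b)/2] * 100."""
    mean = (float(a) + float(b)) / 2.0
    if mean == 0:
        raise MetricUndefinedError("delta_frac undefined for a + b = 0")
    return delta_abs(a, b) / mean * 100.0


def flr(vol: Volume, lesion: RoiMask, liver: RoiMask) -> float:
    """Focal uptake to liver ratio: lesion SUVmax / liver SUVmean."""
    liver_mean = suv_mean(vol, liver)
    if liver_mean <= 0:
        raise MetricUndefinedError(f"liver mean must be > 0 for FLR, got {liver_mean}")
    return suv_max(vol, lesion) / liver_mean


@dataclass
class MetricsReport:
    """Per-ROI metrics for a set of named image types plus pairwise deltas.

    ``suvmax[(image, lesion_label)]`` in g/mL, ``noise[image]`` in percent,
    ``flr[(image, lesion_label)]`` dimensionless. Pairwise entries are keyed
    ``(A, B)`` and satisfy the antisymmetry ``delta(A,B) = -delta(B,A)``.
    """

    suvmax: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    flr: dict = field(default_factory=dict)
    delta_suvmax: dict = field(default_factory=dict)
    frac_suvmax: dict = field(default_factory=dict)
    delta_noise_pp: dict = field(default_factory=dict)
    frac_noise: dict = field(default_factory=dict)

    def rows(self) -> list[dict]:
        """Flatten to one row per (comparison, ROI) for tabular export."""
        out = []
        for (a, b), val in self.frac_suvmax.items():
            lesion = val.keys()
            for lab in lesion:
                out.append(
                    {
                        "comparison": f"{a},{b}",
                        "roi": lab,
                        "metric": "SUVmax",
                        "delta_abs_g_ml": self.delta_suvmax[(a, b)][lab],
                        "delta_frac_percent": self.frac_suvmax[(a, b)][lab],
                    }
                )
        for (a, b), val in self.frac_noise.items():
            out.append(
                {
                    "comparison": f"{a},{b}",
                    "roi": "liver",
                    "metric": "Noise",
                    "delta_abs_pp": self.delta_noise_pp[(a, b)],
                    "delta_frac_percent": val,
                }
            )
        return out


def evaluate_images(images: dict[str, Volume], rois: RoiSet) -> MetricsReport:
    """Compute the full metric block for named image types of one study.

    ``images`` maps type names (e.g. ``"STD"``, ``"BF"``, ``"CNN"``) to
    volumes on a common grid; all ordered pairs are compared.
    """
    rep = MetricsReport()
    names = list(images)
    labels = [m.label or f"lesion{j + 1}" for j, m in enumerate(rois.lesions)]
    for name, vol in images.items():
        rep.noise[name] = noise_level(vol, rois.liver)
        for lab, lesion in zip(labels, rois.lesions):
            rep.suvmax[(name, lab)] = suv_max(vol, lesion)
            rep.flr[(name, lab)] = flr(vol, lesion, rois.liver)
    for a in names:
        for b in names:
            if a == b:
                continue
            rep.delta_suvmax[(a, b)] = {
                lab: delta_abs(rep.suvmax[(a, lab)], rep.suvmax[(b, lab)]) for lab in labels
            }
            rep.frac_suvmax[(a, b)] = {
                lab: delta_frac(rep.suvmax[(a, lab)], rep.suvmax[(b, lab)]) for lab in labels
            }
            rep.delta_noise_pp[(a, b)] = delta_abs(rep.noise[a], rep.noise[b])
            rep.frac_noise[(a, b)] = delta_frac(rep.noise[a], rep.noise[b])
    return rep
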