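"""Volume preprocessing: ADC fitting, intensity normalization, resampling, ROI transfer.

The processing order for a study is: ADC computed on the native DWI grid,
intensity normalization of T1w/T2w (never of ADC maps), B-spline resampling of
all volumes to an isotropic 2 mm grid, then nearest-neighbour propagation of
the T2w ROI to the other grids. Grids are assumed co-registered (shared
physical frame); no registration is performed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .errors import DegenerateInputError, ParameterError

INTENSITY_RANGE = (0.0, 5000.0)
PERCENTILE_ANCHOR = 98.0
TARGET_SPACING = 2.0


@dataclass
class AdcMap:
    """Voxelwise apparent diffusion coefficient (mm^2/s) with a validity flag.

    ``valid`` is False where the log-linear fit was impossible (fewer than two
    positive signal samples); such voxels hold 0 and must be excluded from ROI
    statistics.
    """

    values: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("ADC map contains non-finite values")


def compute_adc(dwi: np.ndarray, b_values, spacing=(1.0, 1.0, 1.0)) -> AdcMap:
    """Fit ADC per voxel as minus the OLS slope of ln S(b) against b.

    ``dwi`` is a 4D stack with the b-value axis first. Nonpositive signal
    samples are excluded from that voxel's fit; voxels left with fewer than two
    valid samples (or without two distinct b among them) are flagged invalid.
    """
    dwi = np.asarray(dwi, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if dwi.ndim != 4 or dwi.shape[0] != b.size:
        raise ParameterError("dwi must be (n_b, x, y, z) matching b_values")
    if b.size < 2 or np.unique(b).size < 2:
        raise ParameterError("need >=2 distinct b-values")
    if np.any(b < 0):
        raise ParameterError("b-values must be nonnegative")

    w = (dwi > 0).astype(float)
    y = np.zeros_like(dwi)
    np.log(dwi, out=y, where=dwi > 0)
    bb = b.reshape(-1, 1, 1, 1)
    n = w.sum(axis=0)
    sx = (w * bb).sum(axis=0)
    sy = (w * y).sum(axis=0)
    sxx = (w * bb**2).sum(axis=0)
    sxy = (w * bb * y).sum(axis=0)
    denom = n * sxx - sx**2
    valid = (n >= 2) & (denom > 0)
    slope = np.zeros_like(denom)
    np.divide(n * sxy - sx * sy, denom, out=slope, where=valid)
    adc = np.where(valid, -slope, 0.0)
    return AdcMap(values=adc, valid=valid, spacing=tuple(float(s) for s in spacing))


def normalize_intensity(
    volume: np.ndarray,
    out_range: tuple[float, float] = INTENSITY_RANGE,
    percentile: float = PERCENTILE_ANCHOR,
) -> np.ndarray:
    """Map [min, p98] of the volume onto [0, 5000], clipping above the anchor.

    Applies to T1w/T2w volumes only; ADC maps are left in physical units. The
    percentile is taken over the whole volume (linear interpolation).
    """
    v = np.asarray(volume, dtype=float)
    lo = float(v.min())
    hi = float(np.percentile(v, percentile))
    if hi <= lo:
        raise DegenerateInputError("volume is constant up to the percentile anchor")
    out = (v - lo) / (hi - lo) * (out_range[1] - out_range[0]) + out_range[0]
    return np.clip(out, out_range[0], out_range[1])


def _to_sitk(volume: np.ndarray, spacing, origin) -> sitk.Image:
    # numpy axis order (x, y, z) -> sitk expects z-fastest from GetImageFromArray
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def resample_isotropic(
    volume: np.ndarray,
    spacing,
    target: float = TARGET_SPACING,
    mode: str = "continuous",
    origin=(0.0, 0.0, 0.0),
):
    """Resample a volume to an isotropic grid (default 2 mm).

    Continuous volumes use cubic B-spline interpolation; binary masks use
    nearest neighbour so the output stays binary. Output extent covers the
    input physical extent. Returns ``(array, new_spacing)``.
    """
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0) or target <= 0:
        raise ParameterError("spacings must be positive")
    if mode not in ("continuous", "mask"):
        raise ParameterError(f"unknown mode {mode!r}")
    vol = np.asarray(volume, dtype=float)
    img = _to_sitk(vol, spacing, origin)
    new_size = [max(1, int(np.ceil(s * sp / target))) for s, sp in zip(vol.shape, spacing)]
    interp = sitk.sitkBSpline if mode == "continuous" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        img,
        new_size,
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (target, target, target),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat64,
        True,  # nearest-neighbour extrapolation at the border
    )
    arr = _from_sitk(out)
    if mode == "mask":
        arr = (arr > 0.5).astype(np.uint8)
    return arr, (target, target, target)


def propagate_roi(
    mask: np.ndarray,
    mask_spacing,
    target_shape,
    target_spacing,
    mask_origin=(0.0, 0.0, 0.0),
    target_origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Transfer a binary ROI to another grid by nearest neighbour in physical space.

    Both grids must live in the same physical frame. Raises if the propagated
    mask is empty (e.g. disjoint physical extents).
    """
    mask = np.asarray(mask) > 0
    mask_spacing = np.asarray(mask_spacing, dtype=float)
    target_spacing = np.asarray(target_spacing, dtype=float)
    if np.any(mask_spacing <= 0) or np.any(target_spacing <= 0):
        raise ParameterError("spacings must be positive")
    out = np.zeros(tuple(target_shape), dtype=np.uint8)
    grids = [
        np.asarray(target_origin)[a] + np.arange(target_shape[a]) * target_spacing[a]
        for a in range(3)
    ]
    idx = [
        np.rint((g - np.asarray(mask_origin)[a]) / mask_spacing[a]).astype(int)
        for a, g in enumerate(grids)
    ]
    ok = [np.clip(i, 0, s - 1) for i, s in zip(idx, mask.shape)]
    inside = [
        (i >= 0) & (i < s) for i, s in zip(idx, mask.shape)
    ]
    ii, jj, kk = np.meshgrid(ok[0], ok[1], ok[2], indexing="ij")
    vi, vj, vk = np.meshgrid(inside[0], inside[1], inside[2], indexing="ij")
    out[...] = mask[ii, jj, kk] & vi & vj & vk
    if not out.any():
        raise DegenerateInputError("propagated ROI is empty on the target grid")
    return out
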