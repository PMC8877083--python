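"""Radiomic feature extraction.

Computes a fixed 536-feature vector per (volume, ROI mask) pair:

* 14 shape/size descriptors of the 3D mask,
* 18 first-order intensity statistics,
* 40 texture features (24 from the grey-level co-occurrence matrix, 16 from
  the grey-level run-length matrix) on the 32-level discretized ROI,
* the same 58 first-order + texture features on each of the 8 sub-bands of a
  first-level undecimated 3D wavelet decomposition (58 x 8 = 464).

Definitions follow the IBSI conventions. Texture matrices are built per 3D
direction (13 unique offsets at distance 1) and features are averaged over
directions. Grey-level discretization uses a fixed bin *count* anchored to the
ROI min/max.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pywt
import trimesh
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy import stats
from skimage import measure

from .errors import DegenerateInputError, SchemaError

_EPS = np.spacing(1.0)

SHAPE_NAMES = [
    "shape_MeshVolume",
    "shape_VoxelVolume",
    "shape_SurfaceArea",
    "shape_SurfaceVolumeRatio",
    "shape_Sphericity",
    "shape_Maximum3DDiameter",
    "shape_Maximum2DDiameterSlice",
    "shape_Maximum2DDiameterColumn",
    "shape_Maximum2DDiameterRow",
    "shape_MajorAxisLength",
    "shape_MinorAxisLength",
    "shape_LeastAxisLength",
    "shape_Elongation",
    "shape_Flatness",
]

FIRSTORDER_NAMES = [
    "firstorder_Energy",
    "firstorder_TotalEnergy",
    "firstorder_Entropy",
    "firstorder_Minimum",
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_Median",
    "firstorder_InterquartileRange",
    "firstorder_Range",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_Kurtosis",
    "firstorder_Variance",
    "firstorder_Uniformity",
]

GLCM_NAMES = [
    "glcm_Autocorrelation",
    "glcm_JointAverage",
    "glcm_ClusterProminence",
    "glcm_ClusterShade",
    "glcm_ClusterTendency",
    "glcm_Contrast",
    "glcm_Correlation",
    "glcm_DifferenceAverage",
    "glcm_DifferenceEntropy",
    "glcm_DifferenceVariance",
    "glcm_Id",
    "glcm_Idm",
    "glcm_Idmn",
    "glcm_Idn",
    "glcm_Imc1",
    "glcm_Imc2",
    "glcm_InverseVariance",
    "glcm_JointEnergy",
    "glcm_JointEntropy",
    "glcm_MCC",
    "glcm_MaximumProbability",
    "glcm_SumAverage",
    "glcm_SumEntropy",
    "glcm_SumSquares",
]

GLRLM_NAMES = [
    "glrlm_GrayLevelNonUniformity",
    "glrlm_GrayLevelNonUniformityNormalized",
    "glrlm_GrayLevelVariance",
    "glrlm_HighGrayLevelRunEmphasis",
    "glrlm_LongRunEmphasis",
    "glrlm_LongRunHighGrayLevelEmphasis",
    "glrlm_LongRunLowGrayLevelEmphasis",
    "glrlm_LowGrayLevelRunEmphasis",
    "glrlm_RunEntropy",
    "glrlm_RunLengthNonUniformity",
    "glrlm_RunLengthNonUniformityNormalized",
    "glrlm_RunPercentage",
    "glrlm_RunVariance",
    "glrlm_ShortRunEmphasis",
    "glrlm_ShortRunHighGrayLevelEmphasis",
    "glrlm_ShortRunLowGrayLevelEmphasis",
]

WAVELET_BANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]

FEATURE_NAMES: list[str] = (
    SHAPE_NAMES
    + FIRSTORDER_NAMES
    + GLCM_NAMES
    + GLRLM_NAMES
    + [
        f"wavelet-{band}_{name}"
        for band in WAVELET_BANDS
        for name in FIRSTORDER_NAMES + GLCM_NAMES + GLRLM_NAMES
    ]
)

N_FEATURES = len(FEATURE_NAMES)  # 536

# 13 unique direction offsets of the 26-neighbourhood (first nonzero positive).
DIRECTIONS_3D = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and next(v for v in d if v != 0) > 0
]


def discretize(values: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Fixed-bin-count grey-level discretization over [min, max] of the ROI.

    Returns integer levels in 1..n_bins; the maximum value is assigned level
    n_bins. A constant ROI yields all ones (single occupied level).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("cannot discretize an empty ROI")
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError("non-finite values in ROI")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass
    return float(pdist(points).max())


def _max_diameter_2d(coords_phys: np.ndarray, fixed_axis: int) -> float:
    """Largest in-plane distance among boundary points, maximised over planes
    perpendicular to ``fixed_axis``."""
    keep = [a for a in range(3) if a != fixed_axis]
    best = 0.0
    for v in np.unique(coords_phys[:, fixed_axis]):
        pts = coords_phys[coords_phys[:, fixed_axis] == v][:, keep]
        if len(pts) >= 2:
            best = max(best, _max_pairwise(pts))
    return best


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """The 14 3D shape/size descriptors of a binary mask on an (an)isotropic grid."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise DegenerateInputError("empty mask")
    spacing = np.asarray(spacing, dtype=float)

    n_vox = int(mask.sum())
    voxel_volume = n_vox * float(np.prod(spacing))

    padded = np.pad(mask.astype(np.uint8), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # Taubin smoothing counters the staircase surface-area overestimate of a
    # voxelized isosurface; skipped for tiny ROIs where it would collapse the mesh
    if len(faces) >= 100:
        trimesh.smoothing.filter_taubin(mesh, iterations=10)
    surface_area = float(mesh.area)
    mesh_volume = float(abs(mesh.volume))

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    # boundary voxel centres in physical coordinates, for diameters
    interior = np.ones_like(mask)
    for ax in range(3):
        for sh in (1, -1):
            interior &= np.roll(np.pad(mask, 1), sh, axis=ax)[1:-1, 1:-1, 1:-1]
    boundary = mask & ~interior
    coords = np.argwhere(boundary if boundary.any() else mask) * spacing

    max3d = _max_pairwise(coords)
    # IBSI plane naming: "Slice" = axial (axes 1,2 vary), etc.
    max2d_slice = _max_diameter_2d(coords, fixed_axis=0)
    max2d_column = _max_diameter_2d(coords, fixed_axis=1)
    max2d_row = _max_diameter_2d(coords, fixed_axis=2)

    all_coords = np.argwhere(mask) * spacing
    if len(all_coords) > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(all_coords.T)))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else np.nan
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else np.nan

    return {
        "shape_MeshVolume": mesh_volume,
        "shape_VoxelVolume": voxel_volume,
        "shape_SurfaceArea": surface_area,
        "shape_SurfaceVolumeRatio": surface_area / mesh_volume,
        "shape_Sphericity": sphericity,
        "shape_Maximum3DDiameter": max3d,
        "shape_Maximum2DDiameterSlice": max2d_slice,
        "shape_Maximum2DDiameterColumn": max2d_column,
        "shape_Maximum2DDiameterRow": max2d_row,
        "shape_MajorAxisLength": major,
        "shape_MinorAxisLength": minor,
        "shape_LeastAxisLength": least,
        "shape_Elongation": elongation,
        "shape_Flatness": flatness,
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_features(
    values: np.ndarray, voxel_volume: float = 1.0, n_bins: int = 32
) -> dict[str, float]:
    """The 18 first-order statistics of the ROI intensities.

    Entropy and uniformity are computed on the ``n_bins``-level discretized
    histogram; a constant ROI therefore has entropy 0 and uniformity 1.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise DegenerateInputError("first-order features need >=1 finite voxel")

    mean = float(x.mean())
    var = 0.0 if x.max() == x.min() else float(x.var())
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    energy = float(np.sum(x**2))

    levels = discretize(x, n_bins)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / x.size
    entropy = float(-np.sum(p * np.log2(p + _EPS)))
    uniformity = float(np.sum(p**2))

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0

    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": voxel_volume * energy,
        "firstorder_Entropy": entropy,
        "firstorder_Minimum": float(x.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_Median": float(med),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_Variance": var,
        "firstorder_Uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_matrix(levels: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset."""
    dx, dy, dz = offset
    sl_a = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip((dx, dy, dz), levels.shape))
    sl_b = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip((dx, dy, dz), levels.shape))
    a, b = levels[sl_a], levels[sl_b]
    ok = mask[sl_a] & mask[sl_b]
    i, j = a[ok] - 1, b[ok] - 1
    counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels).reshape(
        n_levels, n_levels
    )
    return (counts + counts.T).astype(float)


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """24 co-occurrence features, averaged over the 13 distance-1 3D directions.

    Directions with no valid voxel pair are skipped; if no direction produces a
    pair (single-voxel ROI) every feature is returned as NaN (flagged missing).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise DegenerateInputError("empty mask")
    levels, mask = _crop_to_mask(np.asarray(levels), mask)
    per_dir: list[dict[str, float]] = []
    for off in DIRECTIONS_3D:
        P = _glcm_matrix(levels, mask, off, n_levels)
        total = P.sum()
        if total == 0:
            continue
        present = np.where(P.any(axis=0) | P.any(axis=1))[0]
        P = P[np.ix_(present, present)] / total
        iv = (present + 1).astype(float)  # grey-level values of the kept rows
        ng = len(iv)
        I, J = np.meshgrid(iv, iv, indexing="ij")
        px = P.sum(axis=1)
        mu = float((iv * px).sum())          # symmetric: mu_x == mu_y
        sigma2 = float(((iv - mu) ** 2 * px).sum())

        # distributions of |i-j| and i+j over actual grey values
        sum_idx = (np.add.outer(iv, iv)).astype(int)
        p_sum_full = np.bincount(sum_idx.ravel(), weights=P.ravel())
        sum_vals = np.nonzero(p_sum_full)[0].astype(float)
        p_sum = p_sum_full[np.nonzero(p_sum_full)[0]]
        kd_vals = np.unique(np.abs(I - J))
        pd_vals = np.array(
            [P[np.abs(I - J) == k].sum() for k in kd_vals]
        )

        da = float((kd_vals * pd_vals).sum())
        diff_entropy = float(-np.sum(pd_vals * np.log2(pd_vals + _EPS)))
        diff_var = float(((kd_vals - da) ** 2 * pd_vals).sum())

        hxy = float(-np.sum(P * np.log2(P + _EPS)))
        pxpy = np.outer(px, px)
        hxy1 = float(-np.sum(P * np.log2(pxpy + _EPS)))
        hxy2 = float(-np.sum(pxpy * np.log2(pxpy + _EPS)))
        hx = float(-np.sum(px * np.log2(px + _EPS)))
        imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

        if sigma2 > 0:
            corr = float((np.sum(I * J * P) - mu * mu) / sigma2)
        else:
            corr = 1.0

        # MCC: sqrt of second-largest eigenvalue of Q
        with np.errstate(divide="ignore", invalid="ignore"):
            Q = (P[:, None, :] * P[None, :, :] / (px[:, None, None] * px[None, None, :])).sum(
                axis=2
            )
        Q = np.nan_to_num(Q)
        if ng > 1:
            eig = np.sort(np.real(np.linalg.eigvals(Q)))
            mcc = float(np.sqrt(max(0.0, eig[-2])))
        else:
            mcc = 1.0

        off_diag = ~np.eye(ng, dtype=bool)
        inv_var = float(np.sum(P[off_diag] / (I - J)[off_diag] ** 2)) if ng > 1 else 0.0

        per_dir.append(
            {
                "glcm_Autocorrelation": float(np.sum(I * J * P)),
                "glcm_JointAverage": mu,
                "glcm_ClusterProminence": float(np.sum((I + J - 2 * mu) ** 4 * P)),
                "glcm_ClusterShade": float(np.sum((I + J - 2 * mu) ** 3 * P)),
                "glcm_ClusterTendency": float(np.sum((I + J - 2 * mu) ** 2 * P)),
                "glcm_Contrast": float(np.sum((I - J) ** 2 * P)),
                "glcm_Correlation": corr,
                "glcm_DifferenceAverage": da,
                "glcm_DifferenceEntropy": diff_entropy,
                "glcm_DifferenceVariance": diff_var,
                "glcm_Id": float(np.sum(P / (1.0 + np.abs(I - J)))),
                "glcm_Idm": float(np.sum(P / (1.0 + (I - J) ** 2))),
                "glcm_Idmn": float(np.sum(P / (1.0 + (I - J) ** 2 / ng**2))),
                "glcm_Idn": float(np.sum(P / (1.0 + np.abs(I - J) / ng))),
                "glcm_Imc1": imc1,
                "glcm_Imc2": imc2,
                "glcm_InverseVariance": inv_var,
                "glcm_JointEnergy": float(np.sum(P**2)),
                "glcm_JointEntropy": hxy,
                "glcm_MCC": mcc,
                "glcm_MaximumProbability": float(P.max()),
                "glcm_SumAverage": float((sum_vals * p_sum).sum()),
                "glcm_SumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
                "glcm_SumSquares": sigma2,
            }
        )
    if not per_dir:
        return {name: np.nan for name in GLCM_NAMES}
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _glrlm_matrix(levels: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Run-length counts for one direction; masked-out voxels (level 0) break runs."""
    arr = levels
    # orient so the direction has nonnegative steps, then shear into lines
    for ax, d in enumerate(offset):
        if d < 0:
            arr = np.flip(arr, axis=ax)
    offset = tuple(abs(d) for d in offset)
    nx, ny, nz = arr.shape
    coords = np.indices(arr.shape).reshape(3, -1)
    # parameter t along the run direction
    move_axes = [a for a in range(3) if offset[a] != 0]
    t = coords[move_axes[0]]
    # line identifier: coordinates orthogonal to motion, c - t*d, packed per axis
    line_key = np.zeros(coords.shape[1], dtype=np.int64)
    for ax in range(3):
        rel = coords[ax] - t * offset[ax]
        rel -= rel.min()
        line_key = line_key * (nx + ny + nz + 1) + rel
    order = np.lexsort((t, line_key))
    vals = arr.reshape(-1)[order]
    keys = line_key[order]
    # a run ends where the level changes or the line changes
    brk = np.flatnonzero((np.diff(vals) != 0) | (np.diff(keys) != 0)) + 1
    starts = np.concatenate(([0], brk))
    ends = np.concatenate((brk, [vals.size]))
    lv = vals[starts]
    ln = ends - starts
    keep = lv > 0
    R = np.zeros((n_levels, max(nx, ny, nz)), dtype=float)
    np.add.at(R, (lv[keep] - 1, ln[keep] - 1), 1.0)
    return R


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray):
    """Restrict texture computation to the mask bounding box."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def glrlm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> dict[str, float]:
    """16 run-length features averaged over the 13 3D directions."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise DegenerateInputError("empty mask")
    levels, mask = _crop_to_mask(np.asarray(levels), mask)
    lv = np.where(mask, levels, 0).astype(np.int64)
    n_p = float(mask.sum())
    per_dir = []
    for off in DIRECTIONS_3D:
        R = _glrlm_matrix(lv, off, n_levels)
        nr = R.sum()
        if nr == 0:
            continue
        i = np.arange(1, R.shape[0] + 1, dtype=float)[:, None]
        l = np.arange(1, R.shape[1] + 1, dtype=float)[None, :]
        p = R / nr
        r_i = R.sum(axis=1)
        r_l = R.sum(axis=0)
        mu_i = float((np.arange(1, R.shape[0] + 1) * r_i / nr).sum())
        mu_l = float((np.arange(1, R.shape[1] + 1) * r_l / nr).sum())
        pnz = p[p > 0]
        per_dir.append(
            {
                "glrlm_GrayLevelNonUniformity": float((r_i**2).sum() / nr),
                "glrlm_GrayLevelNonUniformityNormalized": float((r_i**2).sum() / nr**2),
                "glrlm_GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
                "glrlm_HighGrayLevelRunEmphasis": float((R * i**2).sum() / nr),
                "glrlm_LongRunEmphasis": float((R * l**2).sum() / nr),
                "glrlm_LongRunHighGrayLevelEmphasis": float((R * i**2 * l**2).sum() / nr),
                "glrlm_LongRunLowGrayLevelEmphasis": float((R * l**2 / i**2).sum() / nr),
                "glrlm_LowGrayLevelRunEmphasis": float((R / i**2).sum() / nr),
                "glrlm_RunEntropy": float(-np.sum(pnz * np.log2(pnz + _EPS))),
                "glrlm_RunLengthNonUniformity": float((r_l**2).sum() / nr),
                "glrlm_RunLengthNonUniformityNormalized": float((r_l**2).sum() / nr**2),
                "glrlm_RunPercentage": float(nr / n_p),
                "glrlm_RunVariance": float((p * (l - mu_l) ** 2).sum()),
                "glrlm_ShortRunEmphasis": float((R / l**2).sum() / nr),
                "glrlm_ShortRunHighGrayLevelEmphasis": float((R * i**2 / l**2).sum() / nr),
                "glrlm_ShortRunLowGrayLevelEmphasis": float((R / (i**2 * l**2)).sum() / nr),
            }
        )
    if not per_dir:
        return {name: np.nan for name in GLRLM_NAMES}
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# wavelet
# ---------------------------------------------------------------------------

def wavelet_bands(volume: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """First-level undecimated (stationary) 3D wavelet decomposition.

    Returns the 8 sub-bands keyed LLL..HHH on the original grid (L = lowpass,
    H = highpass per axis). Odd axes are symmetrically padded to even length
    and cropped back, since the stationary transform requires even extents.
    """
    vol = np.asarray(volume, dtype=float)
    pad = [(0, s % 2) for s in vol.shape]
    padded = np.pad(vol, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    crop = tuple(slice(0, s) for s in vol.shape)
    for key, band in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = band[crop]
    return out


def wavelet_features(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    n_bins: int = 32,
    wavelet: str = "coif1",
) -> dict[str, float]:
    """464 features: 18 FOS + 24 GLCM + 16 GLRLM on each of the 8 wavelet bands."""
    mask = np.asarray(mask) > 0
    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}
    bands = wavelet_bands(volume, wavelet)
    for band_name in WAVELET_BANDS:
        band = bands[band_name]
        roi = band[mask]
        prefix = f"wavelet-{band_name}_"
        fo = first_order_features(roi, voxel_volume=voxel_volume, n_bins=n_bins)
        levels = np.zeros(band.shape, dtype=np.int64)
        levels[mask] = discretize(roi, n_bins)
        gl = glcm_features(levels, mask, n_bins)
        rl = glrlm_features(levels, mask, n_bins)
        for d in (fo, gl, rl):
            for k, v in d.items():
                out[prefix + k] = v
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_all(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    n_bins: int = 32,
    wavelet: str = "coif1",
) -> pd.Series:
    """Extract the full 536-feature vector for one volume/mask pair.

    Shape features are computed once on the original-image mask; intensity and
    texture features on the original image and on each wavelet sub-band.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask) > 0
    if volume.shape != mask.shape:
        raise SchemaError(f"volume {volume.shape} and mask {mask.shape} differ")
    if not mask.any():
        raise DegenerateInputError("empty mask")

    voxel_volume = float(np.prod(spacing))
    roi = volume[mask]
    values: dict[str, float] = {}
    values.update(shape_features(mask, spacing))
    values.update(first_order_features(roi, voxel_volume=voxel_volume, n_bins=n_bins))
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[mask] = discretize(roi, n_bins)
    values.update(glcm_features(levels, mask, n_bins))
    values.update(glrlm_features(levels, mask, n_bins))
    values.update(wavelet_features(volume, mask, spacing, n_bins, wavelet))

    series = pd.Series(values).reindex(FEATURE_NAMES)
    assert len(series) == N_FEATURES
    return series


def delta(post: pd.DataFrame, pre: pd.DataFrame) -> pd.DataFrame:
    """Early-delta feature table: post-cycle-1 minus baseline, element-wise.

    Patients missing either timepoint are dropped; column order must match.
    """
    if list(post.columns) != list(pre.columns):
        raise SchemaError("column names/order differ between timepoints")
    common = post.index.intersection(pre.index)
    return post.loc[common] - pre.loc[common]
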