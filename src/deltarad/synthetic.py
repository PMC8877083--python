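"""Synthetic cohorts with the statistical structure the analysis assumes.

Two generators are provided. The feature-level generator emits ready-made
delta feature tables (one per modality) in which a configurable subset of
columns carries a class effect of given standardized size, the remainder being
block-correlated noise; it is the fast default path for model-selection tests.
The image-level generator emits paired baseline / post-cycle-1 studies with
ellipsoidal tumours whose volume, texture and diffusion change differ by
response class, exercising preprocessing and feature extraction end to end.

Defaults mirror the emulated trial: 50 patients, 25 responders and 25
non-responders, diffusion imaging available for 34 of 50 patients (missing
fraction 0.32), responders shrinking by ~40% in volume after one cycle versus
~5% for non-responders.

A single global seed is expanded into per-patient substreams, so enlarging the
cohort never perturbs the draws of earlier patients.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .features import FEATURE_NAMES, N_FEATURES

MODALITIES = ("t1w", "t2w", "adc")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    effect_size is the standardized mean difference (responders minus
    non-responders, in pooled-SD units) applied to the informative delta
    features; volume_change is the mean fractional post/pre volume change for
    (responders, non-responders).
    """

    n_patients: int = 50
    responder_fraction: float = 0.5
    effect_size: float = 1.5
    n_informative: int = 54  # ~10% of the 536 features
    missing_adc_fraction: float = 0.32  # DWI available for 34/50
    volume_change: tuple[float, float] = (-0.4, -0.05)
    noise_sd: float = 1.0
    intra_block_corr: float = 0.3
    block_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ParameterError("need at least 2 patients")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ParameterError("responder_fraction must be in (0, 1)")
        n_resp = int(round(self.n_patients * self.responder_fraction))
        if n_resp < 1 or self.n_patients - n_resp < 1:
            raise ParameterError("each class needs >=1 patient")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be nonnegative")
        if not 0 <= self.n_informative <= N_FEATURES:
            raise ParameterError(f"n_informative must be in [0, {N_FEATURES}]")
        if not 0.0 <= self.missing_adc_fraction < 1.0:
            raise ParameterError("missing_adc_fraction must be in [0, 1)")
        if self.noise_sd <= 0 and self.effect_size > 0:
            raise ParameterError("noise_sd must be positive")
        for vc in self.volume_change:
            if 1.0 + vc <= 0.0:
                raise ParameterError("volume_change implies non-positive volume")

    @property
    def n_responders(self) -> int:
        return int(round(self.n_patients * self.responder_fraction))


@dataclass
class ImagingStudy:
    """One patient's volumes and ROI mask at one timepoint.

    The ROI mask lives on the T2w grid. The DWI stack, if present, is 4D with
    the b-value axis first and must come with >=2 strictly increasing b-values.
    """

    patient_id: str
    timepoint: str  # "baseline" | "post_cycle1"
    t1w: np.ndarray | None
    t1w_spacing: tuple[float, float, float] | None
    t2w: np.ndarray = None
    t2w_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_mask: np.ndarray = None
    dwi: np.ndarray | None = None
    b_values: tuple[float, ...] | None = None
    dwi_spacing: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.timepoint not in ("baseline", "post_cycle1"):
            raise ParameterError(f"unknown timepoint {self.timepoint!r}")
        if self.roi_mask is None or not (np.asarray(self.roi_mask) > 0).any():
            raise ParameterError("roi_mask must have >=1 foreground voxel")
        if np.asarray(self.roi_mask).shape != np.asarray(self.t2w).shape:
            raise ParameterError("roi_mask must live on the t2w grid")
        if (self.dwi is None) != (self.b_values is None):
            raise ParameterError("dwi and b_values must be given together")
        if self.b_values is not None:
            b = np.asarray(self.b_values, dtype=float)
            if b.size < 2 or np.any(np.diff(b) <= 0) or np.any(b < 0):
                raise ParameterError("b_values must be >=2, nonnegative, strictly increasing")


def _labels(spec: CohortSpec) -> np.ndarray:
    y = np.zeros(spec.n_patients, dtype=int)
    y[: spec.n_responders] = 1
    return y


def _adc_availability(spec: CohortSpec, root: np.random.SeedSequence) -> np.ndarray:
    """Exactly round(n * (1 - missing_fraction)) patients get diffusion imaging."""
    n_avail = int(round(spec.n_patients * (1.0 - spec.missing_adc_fraction)))
    rng = np.random.default_rng(root.spawn(1)[0])
    u = rng.random(spec.n_patients)
    avail = np.zeros(spec.n_patients, dtype=bool)
    avail[np.argsort(u)[:n_avail]] = True
    return avail


def generate_feature_cohort(spec: CohortSpec):
    """Labeled delta feature tables (one per modality) plus availability mask.

    Returns ``(tables, labels, availability)`` where ``tables`` maps modality
    to a patients x 536 DataFrame of delta features, ``labels`` is a Series
    (1 = responder), and ``availability`` is a boolean patients x modality
    DataFrame (ADC rows absent from its table for unavailable patients).

    Informative columns get a mean shift of ``effect_size * noise_sd`` for
    responders; all columns share a block structure with intra-block
    correlation ``intra_block_corr``.
    """
    y = _labels(spec)
    ids = [f"P{i:03d}" for i in range(spec.n_patients)]
    root = np.random.SeedSequence(spec.seed)
    avail_ss, meta_ss = root.spawn(2)
    avail = _adc_availability(spec, avail_ss)

    meta_rng = np.random.default_rng(meta_ss)
    informative = {
        m: np.sort(meta_rng.choice(N_FEATURES, size=spec.n_informative, replace=False))
        for m in MODALITIES
    }

    rho = spec.intra_block_corr
    n_blocks = int(np.ceil(N_FEATURES / spec.block_size))
    block_of = np.arange(N_FEATURES) // spec.block_size

    # children 0 and 1 of the root sequence are the cohort-level streams above;
    # patient substreams start at child 2, so growing the cohort only appends
    patient_seeds = np.random.SeedSequence(spec.seed).spawn(2 + spec.n_patients)[2:]

    tables = {}
    for mi, m in enumerate(MODALITIES):
        rows = np.empty((spec.n_patients, N_FEATURES))
        for p in range(spec.n_patients):
            rng = np.random.default_rng(patient_seeds[p].spawn(len(MODALITIES))[mi])
            factors = rng.standard_normal(n_blocks)
            eps = rng.standard_normal(N_FEATURES)
            x = np.sqrt(rho) * factors[block_of] + np.sqrt(1.0 - rho) * eps
            rows[p] = x * spec.noise_sd
            if y[p] == 1:
                rows[p, informative[m]] += spec.effect_size * spec.noise_sd
        df = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"), columns=FEATURE_NAMES)
        if m == "adc":
            df = df.loc[avail]
        tables[m] = df

    labels = pd.Series(y, index=pd.Index(ids, name="patient_id"), name="label")
    availability = pd.DataFrame(
        {"t1w": True, "t2w": True, "adc": avail},
        index=pd.Index(ids, name="patient_id"),
    )
    return tables, labels, availability


# ---------------------------------------------------------------------------
# image-level generator
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    d = (
        ((X - center_mm[0]) / radii_mm[0]) ** 2
        + ((Y - center_mm[1]) / radii_mm[1]) ** 2
        + ((Z - center_mm[2]) / radii_mm[2]) ** 2
    )
    return d <= 1.0


def _gaussian_random_field(rng, shape, corr_len_vox: float) -> np.ndarray:
    """Unit-variance spatially correlated noise (smoothed white noise)."""
    w = rng.standard_normal(shape)
    if corr_len_vox <= 0:
        return w
    f = ndimage.gaussian_filter(w, corr_len_vox, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_imaging_cohort(
    spec: CohortSpec,
    shape=(48, 48, 32),
    spacing=(1.5, 1.5, 2.0),
    b_values=(0.0, 500.0, 1000.0),
    adc_baseline: float = 1.0e-3,
    adc_change: tuple[float, float] = (0.35, 0.05),
    texture_contrast: float = 0.25,
    adc_texture: float = 0.1,
    dwi_noise_fraction: float = 0.01,
):
    """Paired baseline / post-cycle-1 studies per patient, plus labels.

    Tumours are ellipsoids with Gaussian-random-field interior texture whose
    contrast and correlation length shift at post-cycle-1 for responders.
    Responder post-cycle-1 ROI volume is scaled by ``1 + volume_change[0]``
    (non-responders by ``1 + volume_change[1]``). DWI stacks follow
    S(b) = S0 exp(-ADC b) with a class-dependent ADC increase and
    ``noise_sd * dwi_noise_fraction`` relative noise; DWI is omitted for the
    configured fraction of patients.
    """
    y = _labels(spec)
    root = np.random.SeedSequence(spec.seed)
    avail_ss, _ = root.spawn(2)
    avail = _adc_availability(spec, avail_ss)
    patient_seeds = np.random.SeedSequence(spec.seed).spawn(2 + spec.n_patients)[2:]

    spacing = tuple(float(s) for s in spacing)
    extent = [shape[a] * spacing[a] for a in range(3)]
    studies = []
    for p in range(spec.n_patients):
        rng = np.random.default_rng(patient_seeds[p])
        pid = f"P{p:03d}"
        center = [extent[a] / 2 + rng.uniform(-2, 2) for a in range(3)]
        radii = np.array([rng.uniform(8.0, 12.0) for _ in range(3)])
        vc = spec.volume_change[0] if y[p] == 1 else spec.volume_change[1]
        radii_post = radii * (1.0 + vc) ** (1.0 / 3.0)

        pair = []
        for tp, r in (("baseline", radii), ("post_cycle1", radii_post)):
            mask = _ellipsoid_mask(shape, spacing, center, r)
            if not mask.any():
                mask_idx = tuple(int(c / s) for c, s in zip(center, spacing))
                mask = np.zeros(shape, dtype=bool)
                mask[mask_idx] = True

            # texture: responders lose contrast and coherence after cycle 1
            if tp == "post_cycle1" and y[p] == 1:
                contrast, corr_len = texture_contrast * 0.5, 0.8
            else:
                contrast, corr_len = texture_contrast, 1.6
            noise = spec.noise_sd

            def mri_volume(tumor_mean, bg_mean, sub_rng):
                grf = _gaussian_random_field(sub_rng, shape, corr_len)
                vol = np.full(shape, bg_mean, dtype=float)
                vol += 10.0 * sub_rng.standard_normal(shape) * (noise > 0)
                vol[mask] = tumor_mean * (1.0 + contrast * grf[mask])
                return np.clip(vol, 0.0, None)

            t1w = mri_volume(300.0, 120.0, np.random.default_rng(rng.integers(2**31)))
            t2w = mri_volume(400.0, 150.0, np.random.default_rng(rng.integers(2**31)))

            dwi = None
            bvals = None
            if avail[p]:
                ac = adc_change[0] if y[p] == 1 else adc_change[1]
                factor = 1.0 + (ac if tp == "post_cycle1" else 0.0)
                grf = _gaussian_random_field(
                    np.random.default_rng(rng.integers(2**31)), shape, corr_len
                )
                adc_field = adc_baseline * factor * (1.0 + adc_texture * grf)
                adc_field = np.clip(adc_field, 1e-5, None)
                s0 = np.where(mask, 800.0, 400.0)
                b = np.asarray(b_values, dtype=float)
                dwi = s0[None] * np.exp(-adc_field[None] * b.reshape(-1, 1, 1, 1))
                if spec.noise_sd > 0 and dwi_noise_fraction > 0:
                    nrng = np.random.default_rng(rng.integers(2**31))
                    dwi = dwi * (
                        1.0
                        + spec.noise_sd
                        * dwi_noise_fraction
                        * nrng.standard_normal(dwi.shape)
                    )
                    dwi = np.clip(dwi, 1e-6, None)
                bvals = tuple(float(x) for x in b)

            pair.append(
                ImagingStudy(
                    patient_id=pid,
                    timepoint=tp,
                    t1w=t1w,
                    t1w_spacing=spacing,
                    t2w=t2w,
                    t2w_spacing=spacing,
                    roi_mask=mask.astype(np.uint8),
                    dwi=dwi,
                    b_values=bvals,
                    dwi_spacing=spacing,
                )
            )
        studies.append(tuple(pair))

    ids = [f"P{i:03d}" for i in range(spec.n_patients)]
    labels = pd.Series(y, index=pd.Index(ids, name="patient_id"), name="label")
    return studies, labels


def generate_recist_calls(
    labels: pd.Series,
    miss_rate_responders: float = 0.4,
    miss_rate_nonresponders: float = 0.04,
    seed: int = 0,
) -> pd.Series:
    """Synthetic early radiological calls with class-dependent error rates.

    Default rates mirror an early read that misses 40% of eventual responders
    but almost never mislabels a non-responder.
    """
    rng = np.random.default_rng(seed)
    calls = []
    for lab in labels:
        if lab == 1:
            calls.append(0 if rng.random() < miss_rate_responders else 1)
        else:
            calls.append(1 if rng.random() < miss_rate_nonresponders else 0)
    return pd.Series(calls, index=labels.index, name="early_recist")
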