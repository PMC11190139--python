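"""Synthetic cortical phantoms and cohort generation.

Two simulation tiers back the test and calibration machinery:

* **voxel tier** — :func:`make_cortical_phantom` builds a 3D cortical slab
  (WM | GM ribbon | CSF, optional sinusoidal boundary undulation) with
  known depth-dependent T1/T2* ground truth, and
  :func:`render_subject_images` forward-simulates the MP2RAGEME images so
  the full map-estimation and laminar-sampling chain can be exercised;
* **profile tier** — :func:`simulate_profile_cohort` draws the 10-depth
  profiles directly, which keeps thousand-replicate statistical
  calibrations cheap.

The cohort generator emulates a 7T case-control study of depression:
48 patients (MDD) and 10 controls (HC) matched on age and sex, a severity
score (IDS), childhood-trauma score (CTQ), medication and comorbidity
flags, and a per-subject additive T1 offset in one affected region whose
population statistics are calibrated to a target standardized group
difference (Cohen's d, default 0.6) and a target within-patient
severity correlation (default 0.27).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mp2rageme import AcquisitionParams, simulate_mp2rage_signals, uni_contrast

__all__ = [
    "BACKGROUND",
    "WM",
    "GM",
    "CSF",
    "ROI_CODES",
    "ROI_NAMES",
    "BASELINE_COEFFS",
    "TISSUE_DEFAULTS",
    "PhantomTruth",
    "SubjectSpec",
    "EffectConfig",
    "GeometryError",
    "CalibrationError",
    "baseline_profile",
    "baseline_mean",
    "make_cortical_phantom",
    "generate_cohort",
    "cohort_frame",
    "render_subject_images",
    "simulate_profile_cohort",
]

BACKGROUND, WM, GM, CSF = 0, 1, 2, 3

ROI_CODES = {"rACC": 1, "mOFC": 2, "lOFC": 3, "S1": 4}
ROI_NAMES = {v: k for k, v in ROI_CODES.items()}

# cubic depth profiles (constant, linear, quadratic, cubic coefficient) over
# normalized depth in [0,1]; T1 rises from the WM/GM boundary toward CSF
# (less myelin superficially), chosen so the control GM ribbon averages
# 1860 ms with a boundary value of 1745 ms, within the 1200-2000 ms 7T
# cortical regime; T2* ~ 26-30 ms across the ribbon.
BASELINE_COEFFS = {
    "T1": (1745.0, 190.0, 90.0, -40.0),
    "T2star": (26.0, 4.0, 0.0, 0.0),
}

# literature-typical 7T values for the non-cortical compartments
TISSUE_DEFAULTS = {
    "t1_wm": 1200.0,
    "t1_csf": 4000.0,
    "t2star_wm": 27.0,
    "t2star_csf": 100.0,
}


class GeometryError(ValueError):
    """Requested phantom geometry cannot be represented on the grid."""


class CalibrationError(ValueError):
    """Requested effect-size / correlation combination is infeasible."""


@dataclass
class PhantomTruth:
    """Voxelwise ground truth for one synthetic cortical slab."""

    labels: np.ndarray  # {BACKGROUND, WM, GM, CSF}
    roi_labels: np.ndarray  # {0} | ROI_CODES values, subset of GM
    depth_truth: np.ndarray  # [0,1] in GM, NaN elsewhere
    t1_truth: np.ndarray  # ms
    t2star_truth: np.ndarray  # ms
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)

    def roi_mask(self, roi: str, hemisphere: str) -> np.ndarray:
        """Boolean mask of one ROI in one hemisphere (split along axis 0)."""
        if hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        half = self.labels.shape[0] // 2
        mask = self.roi_labels == ROI_CODES[roi]
        sl = slice(0, half) if hemisphere == "left" else slice(half, None)
        out = np.zeros_like(mask)
        out[sl] = mask[sl]
        return out


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    group: str  # 'MDD' | 'HC'
    age: float
    sex: str  # 'F' | 'M'
    ids_score: float  # NaN if not completed
    ctq_score: float
    on_antidepressants: bool
    comorbid_anxiety: bool
    t1_profile_shift: float  # true additive T1 offset (ms) in the affected ROI
    rng_seed: int


@dataclass(frozen=True)
class EffectConfig:
    """Generative effect structure of the synthetic cohort."""

    affected_roi: str = "lOFC"
    group_shift_d: float = 0.6
    severity_corr: float = 0.27
    between_subject_sd: float = 70.0  # ms, matches printed metric SDs
    noise_sd: float = 0.01  # image-domain noise, fraction of signal
    depth_weighted: bool = False  # weight the shift by 2*depth instead of 1
    profile_noise_sd_t1: float = 25.0  # ms per depth sample (profile tier)
    profile_noise_sd_t2s: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.severity_corr) >= 1:
            raise CalibrationError("|severity_corr| must be < 1")
        if self.between_subject_sd <= 0:
            raise CalibrationError("between_subject_sd must be > 0")
        if self.affected_roi not in ROI_CODES:
            raise ValueError(f"unknown ROI {self.affected_roi!r}")


def baseline_profile(depth, contrast: str = "T1", coeffs: Sequence[float] | None = None):
    """Healthy-control quantitative value (ms) at normalized cortical depth.

    A smooth monotone-increasing cubic in depth (0 = WM/GM boundary,
    1 = GM/CSF boundary); see :data:`BASELINE_COEFFS` for the defaults.
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("depth must lie in [0, 1]")
    if coeffs is None:
        coeffs = BASELINE_COEFFS[contrast]
    a, b, c, e = coeffs
    return a + b * d + c * d**2 + e * d**3


def baseline_mean(contrast: str = "T1", coeffs: Sequence[float] | None = None) -> float:
    """Closed-form ribbon average of the baseline cubic over depth [0,1]."""
    if coeffs is None:
        coeffs = BASELINE_COEFFS[contrast]
    a, b, c, e = coeffs
    return a + b / 2 + c / 3 + e / 4


def make_cortical_phantom(
    grid_shape: tuple[int, int, int] = (64, 64, 32),
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7),
    ribbon_thickness_mm: float = 8.4,
    spec: SubjectSpec | None = None,
    effects: EffectConfig | None = None,
    undulation_amp_mm: float = 0.7,
    undulation_period_mm: float = 22.4,
    tissue: dict | None = None,
) -> PhantomTruth:
    """Build a WM | GM | CSF slab phantom with known laminar structure.

    The GM ribbon runs along the last axis; the WM/GM boundary optionally
    undulates sinusoidally in-plane, which spreads the sampled depths over
    the full [0, 1] range.  If ``spec`` carries a nonzero
    ``t1_profile_shift`` it is added to the T1 truth inside the affected
    ROI (uniform in depth, or weighted by ``2 * depth`` when
    ``effects.depth_weighted``).  ROIs tile the second axis in four strips
    (rACC, mOFC, lOFC, S1); hemispheres split the first axis.
    """
    effects = effects or EffectConfig()
    tissue = {**TISSUE_DEFAULTS, **(tissue or {})}
    nx, ny, nz = grid_shape
    dz = voxel_size[2]
    th = ribbon_thickness_mm / dz
    if th < 4:
        raise GeometryError("cortical ribbon must span at least 4 voxels")

    x = np.arange(nx)[:, None, None] * voxel_size[0]
    y = np.arange(ny)[None, :, None] * voxel_size[1]
    z = np.arange(nz)[None, None, :]

    amp = undulation_amp_mm / dz
    zw0 = (nz - th) / 2.0
    if zw0 - amp < 1 or zw0 + th + amp > nz - 1:
        raise GeometryError("grid too thin for ribbon plus WM/CSF margins")
    k = 2 * np.pi / undulation_period_mm
    zw = zw0 + amp * np.sin(k * x) * np.cos(k * y)  # (nx, ny, 1)

    labels = np.full(grid_shape, CSF, dtype=np.int8)
    labels[np.broadcast_to(z < zw, grid_shape)] = WM
    gm = (z >= zw) & (z < zw + th)
    labels[np.broadcast_to(gm, grid_shape)] = GM
    gm = labels == GM

    depth = (z - zw + 0.5) / th
    depth = np.clip(np.broadcast_to(depth, grid_shape), 0.0, 1.0).copy()
    depth[~gm] = np.nan

    roi_labels = np.zeros(grid_shape, dtype=np.int8)
    strip = ny // 4
    for i, roi in enumerate(("rACC", "mOFC", "lOFC", "S1")):
        sel = np.zeros(grid_shape, dtype=bool)
        sel[:, i * strip : (i + 1) * strip if i < 3 else ny, :] = True
        roi_labels[sel & gm] = ROI_CODES[roi]

    t1 = np.full(grid_shape, tissue["t1_wm"], dtype=float)
    t1[labels == CSF] = tissue["t1_csf"]
    t1[gm] = baseline_profile(depth[gm], "T1")
    t2s = np.full(grid_shape, tissue["t2star_wm"], dtype=float)
    t2s[labels == CSF] = tissue["t2star_csf"]
    t2s[gm] = baseline_profile(depth[gm], "T2star")

    if spec is not None and spec.t1_profile_shift != 0.0:
        aff = (roi_labels == ROI_CODES[effects.affected_roi]) & gm
        w = 2.0 * depth[aff] if effects.depth_weighted else 1.0
        t1[aff] += spec.t1_profile_shift * w

    return PhantomTruth(
        labels=labels,
        roi_labels=roi_labels,
        depth_truth=depth,
        t1_truth=t1,
        t2star_truth=t2s,
        voxel_size=voxel_size,
    )


def _truncnorm(rng, n, loc, scale, lo, hi):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return sps.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


# severity-score distribution bounds (IDS range 0-84) and population moments
_IDS_MDD = dict(loc=33.5, scale=13.5, lo=9.0, hi=84.0)
_IDS_HC = dict(loc=4.0, scale=3.0, lo=0.0, hi=84.0)


def _ids_population_moments():
    p = _IDS_MDD
    a, b = (p["lo"] - p["loc"]) / p["scale"], (p["hi"] - p["loc"]) / p["scale"]
    m, v = sps.truncnorm.stats(a, b, loc=p["loc"], scale=p["scale"], moments="mv")
    return float(m), float(np.sqrt(v))


def generate_cohort(
    n_mdd: int = 48,
    n_hc: int = 10,
    effects: EffectConfig | None = None,
    master_seed: int = 0,
    n_missing_ids: int = 1,
) -> list[SubjectSpec]:
    """Draw a reproducible synthetic case-control cohort.

    Ages ~ Normal(37, 10) truncated to the study's 20-55 year inclusion
    window, ~70% female.  Patient severity (IDS) ~ Normal(33.5, 13.5)
    truncated to >= 9; control IDS ~ Normal(4, 3) truncated to >= 0.  The
    per-subject T1 offset in the affected ROI is

        HC:   shift = sigma_b * eps
        MDD:  shift = d * sigma_b  +  rho * sigma_b * z_ids
                      + sqrt(1 - rho^2) * sigma_b * eta

    with ``z_ids`` the severity score standardized by its population
    (truncated-normal) moments and eps, eta independent standard normals,
    so both groups have shift SD ``sigma_b`` exactly, the standardized
    group difference equals ``group_shift_d`` and the within-patient
    Pearson correlation between shift and severity equals
    ``severity_corr`` in population.  ``n_missing_ids`` patients (default
    one, mirroring typical incomplete questionnaires) have their IDS and
    CTQ scores masked after the shift is drawn.
    """
    if n_mdd < 1 or n_hc < 1:
        raise ValueError("need at least one subject per group")
    effects = effects or EffectConfig()
    rho = effects.severity_corr
    sb = effects.between_subject_sd
    delta = effects.group_shift_d * sb
    rng = np.random.default_rng(master_seed)

    n = n_mdd + n_hc
    groups = np.array(["MDD"] * n_mdd + ["HC"] * n_hc)
    ages = _truncnorm(rng, n, 37.0, 10.0, 20.0, 55.0)
    sexes = np.where(rng.random(n) < 0.7, "F", "M")

    ids = np.empty(n)
    ids[:n_mdd] = _truncnorm(rng, n_mdd, **{
        "loc": _IDS_MDD["loc"], "scale": _IDS_MDD["scale"],
        "lo": _IDS_MDD["lo"], "hi": _IDS_MDD["hi"],
    })
    ids[n_mdd:] = _truncnorm(rng, n_hc, **{
        "loc": _IDS_HC["loc"], "scale": _IDS_HC["scale"],
        "lo": _IDS_HC["lo"], "hi": _IDS_HC["hi"],
    })
    ctq = np.empty(n)
    ctq[:n_mdd] = _truncnorm(rng, n_mdd, 46.8, 19.2, 25.0, 125.0)
    ctq[n_mdd:] = _truncnorm(rng, n_hc, 39.9, 9.2, 25.0, 125.0)
    meds = np.concatenate([rng.random(n_mdd) < 0.5, np.zeros(n_hc, dtype=bool)])
    anx = np.concatenate([rng.random(n_mdd) < 0.44, np.zeros(n_hc, dtype=bool)])

    mu_ids, sd_ids = _ids_population_moments()
    z = (ids[:n_mdd] - mu_ids) / sd_ids
    eta = rng.standard_normal(n_mdd)
    eps = rng.standard_normal(n_hc)
    shift = np.empty(n)
    shift[:n_mdd] = delta + rho * sb * z + np.sqrt(1.0 - rho**2) * sb * eta
    shift[n_mdd:] = sb * eps

    seeds = rng.integers(0, 2**31 - 1, size=n)
    missing = rng.choice(n_mdd, size=min(n_missing_ids, n_mdd), replace=False)
    ids = ids.copy()
    ctq = ctq.copy()
    ids[missing] = np.nan
    ctq[missing] = np.nan

    return [
        SubjectSpec(
            subject_id=f"sub-{i + 1:03d}",
            group=str(groups[i]),
            age=float(ages[i]),
            sex=str(sexes[i]),
            ids_score=float(ids[i]),
            ctq_score=float(ctq[i]),
            on_antidepressants=bool(meds[i]),
            comorbid_anxiety=bool(anx[i]),
            t1_profile_shift=float(shift[i]),
            rng_seed=int(seeds[i]),
        )
        for i in range(n)
    ]


def cohort_frame(cohort: Sequence[SubjectSpec]) -> pd.DataFrame:
    """One-row-per-subject DataFrame view of a cohort."""
    return pd.DataFrame([s.__dict__ for s in cohort])


def render_subject_images(
    truth: PhantomTruth,
    params: AcquisitionParams | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    pd_scale: float = 1000.0,
) -> dict:
    """Forward-simulate the MP2RAGEME images for one phantom.

    Returns signed first-inversion and second-inversion (first-echo)
    volumes, the four echo-magnitude volumes of the second readout, and
    the UNI volume computed from the noisy signed pair.  Gaussian noise of
    standard deviation ``noise_sd`` times the local noiseless signal is
    added independently per image; fully deterministic given ``seed``.
    """
    params = params or AcquisitionParams()
    rng = np.random.default_rng(seed)
    s1, s2 = simulate_mp2rage_signals(truth.t1_truth, params)
    te1 = params.TEs[0]
    t2s = truth.t2star_truth
    decay1 = np.exp(-te1 / t2s)

    def noisy(img):
        if noise_sd == 0:
            return img.copy()
        return img + rng.normal(0.0, noise_sd * np.abs(img))

    inv1 = noisy(pd_scale * s1 * decay1)
    inv2 = noisy(pd_scale * s2 * decay1)
    echoes = [
        noisy(pd_scale * np.abs(s2) * np.exp(-te / t2s)) for te in params.TEs
    ]
    uni = uni_contrast(inv1, inv2)
    return {"inv1": inv1, "inv2": inv2, "echoes": echoes, "uni": uni}


_BIN_CENTERS = (np.arange(10) + 0.5) / 10


def simulate_profile_cohort(
    cohort: Sequence[SubjectSpec],
    effects: EffectConfig | None = None,
    seed: int = 0,
    rois: Sequence[str] = ("rACC", "mOFC", "lOFC", "S1"),
    contrasts: Sequence[str] = ("T1", "T2star"),
    hemispheres: Sequence[str] = ("left", "right"),
    n_depths: int = 10,
    lateralized_shift: float = 0.0,
) -> pd.DataFrame:
    """Draw 10-depth profiles directly (fast tier for calibration loops).

    Each profile is the baseline cubic at the bin centers, plus the
    subject's T1 offset in the affected ROI, plus i.i.d. Gaussian
    measurement noise per depth sample.  ``lateralized_shift`` adds a
    left-hemisphere-only T1 offset in the affected ROI (for
    lateralization power checks).  Returns a long-format DataFrame with
    one row per (subject, roi, hemisphere, contrast, depth bin).
    """
    effects = effects or EffectConfig()
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_depths) + 0.5) / n_depths
    rows = []
    for s in cohort:
        for roi in rois:
            for contrast in contrasts:
                base = baseline_profile(centers, contrast)
                noise_sd = (
                    effects.profile_noise_sd_t1
                    if contrast == "T1"
                    else effects.profile_noise_sd_t2s
                )
                shift = np.zeros(n_depths)
                if contrast == "T1" and roi == effects.affected_roi:
                    w = 2.0 * centers if effects.depth_weighted else 1.0
                    shift = s.t1_profile_shift * np.ones(n_depths) * w
                for hemi in hemispheres:
                    vals = base + shift + rng.normal(0.0, noise_sd, n_depths)
                    if (
                        hemi == "left"
                        and contrast == "T1"
                        and roi == effects.affected_roi
                    ):
                        vals = vals + lateralized_shift
                    rows.append((s.subject_id, roi, hemi, contrast, vals))
    n_prof = len(rows)
    rep = np.repeat
    return pd.DataFrame(
        {
            "subject_id": rep([r[0] for r in rows], n_depths),
            "roi": rep([r[1] for r in rows], n_depths),
            "hemisphere": rep([r[2] for r in rows], n_depths),
            "contrast": rep([r[3] for r in rows], n_depths),
            "depth_bin": np.tile(np.arange(1, n_depths + 1), n_prof),
            "depth": np.tile(centers, n_prof),
            "value": np.concatenate([r[4] for r in rows]),
            "n_voxels": np.full(n_prof * n_depths, 100),
        }
    )
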