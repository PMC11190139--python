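"""MP2RAGEME signal model, T1 lookup inversion and multi-echo T2* fitting.

The MP2RAGEME sequence acquires two rapid gradient-echo (GRE) readout
blocks after an adiabatic inversion pulse; the second block is multi-echo.
Longitudinal magnetization follows a periodic steady state: inversion,
free recovery, a train of small-flip excitations (block 1), free recovery,
a second train (block 2), free recovery, repeat.  The two block signals
combine into the bias-field-insensitive UNI contrast

    UNI = S1 * S2 / (S1**2 + S2**2)   in [-0.5, 0.5],

which is monotone in T1 over a usable branch, so T1 is recovered by a
lookup table.  T2* is recovered from the monoexponential decay across the
echoes of the second block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionParams",
    "LookupTable",
    "QuantMap",
    "InvalidParameterError",
    "UndefinedContrastError",
    "ResolutionError",
    "simulate_mp2rage_signals",
    "uni_contrast",
    "build_t1_lookup",
    "estimate_t1_map",
    "simulate_multiecho_decay",
    "estimate_t2star_map",
]


class InvalidParameterError(ValueError):
    """Acquisition parameters admit no physical periodic steady state."""


class UndefinedContrastError(ValueError):
    """UNI contrast undefined (both block signals zero)."""


class ResolutionError(ValueError):
    """Lookup grid too coarse to establish a monotone branch."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and flip-angle parameters of an MP2RAGEME acquisition.

    All times in milliseconds, flip angles in degrees.  ``TI1``/``TI2`` are
    the inversion times at the k-space centers of the two GRE blocks,
    ``TR_gre1``/``TR_gre2`` the excitation spacings within each block,
    ``TR_seq`` the full-sequence repetition time, ``TEs`` the echo times of
    the second (multi-echo) block, ``n_exc`` the excitations per block
    (turbo factor) and ``inv_eff`` the inversion-pulse efficiency: the
    fraction of longitudinal magnetization actually inverted, so the pulse
    acts as mz -> (1 - 2*inv_eff)*mz (1 = ideal inversion, 0 = no pulse).
    """

    TI1: float = 670.0
    TI2: float = 3675.4
    TR_seq: float = 6778.0
    TR_gre1: float = 6.2
    TR_gre2: float = 31.0
    FA1: float = 4.0
    FA2: float = 4.0
    TEs: tuple[float, ...] = (3.0, 11.5, 19.0, 28.5)
    n_exc: int = 150
    inv_eff: float = 0.96

    def __post_init__(self) -> None:
        if not (0 < self.TI1 < self.TI2 < self.TR_seq):
            raise ValueError("require 0 < TI1 < TI2 < TR_seq")
        tes = tuple(float(t) for t in self.TEs)
        if any(t < 0 for t in tes) or any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("TEs must be non-negative and strictly increasing")
        object.__setattr__(self, "TEs", tes)
        for fa in (self.FA1, self.FA2):
            if not (0 < fa < 90):
                raise ValueError("flip angles must lie in (0, 90) degrees")
        if self.n_exc < 1:
            raise ValueError("n_exc must be >= 1")
        if not (0.0 <= self.inv_eff <= 1.0):
            raise ValueError("inv_eff must lie in [0, 1]")
        # free-recovery gaps must be non-negative for the timing to be physical
        if min(self.gaps) < -1e-9:
            raise ValueError(
                "readout blocks do not fit between the inversion times "
                f"(gaps {self.gaps})"
            )

    @property
    def gaps(self) -> tuple[float, float, float]:
        """Free-recovery durations (TA, TB, TC) around the two blocks."""
        half1 = 0.5 * self.n_exc * self.TR_gre1
        half2 = 0.5 * self.n_exc * self.TR_gre2
        ta = self.TI1 - half1
        tb = self.TI2 - half2 - (self.TI1 + half1)
        tc = self.TR_seq - (self.TI2 + half2)
        return (ta, tb, tc)


@dataclass(frozen=True)
class LookupTable:
    """Tabulated UNI(T1) with its largest strictly monotone branch."""

    t1_grid: np.ndarray
    uni_grid: np.ndarray
    valid_range: tuple[float, float]  # (t1_lo, t1_hi) of the monotone branch
    _lo: int = field(repr=False, default=0)
    _hi: int = field(repr=False, default=0)  # inclusive index bounds

    @property
    def uni_bounds(self) -> tuple[float, float]:
        """(min, max) UNI attainable on the monotone branch."""
        seg = self.uni_grid[self._lo : self._hi + 1]
        return float(seg.min()), float(seg.max())

    def invert(self, uni: np.ndarray) -> np.ndarray:
        """Map UNI values to T1 (ms) on the monotone branch; NaN outside."""
        uni = np.asarray(uni, dtype=float)
        u = self.uni_grid[self._lo : self._hi + 1]
        t = self.t1_grid[self._lo : self._hi + 1]
        if u[0] > u[-1]:  # np.interp needs ascending x
            u, t = u[::-1], t[::-1]
        lo, hi = float(u[0]), float(u[-1])
        out = np.interp(uni, u, t)
        out = np.where((uni >= lo) & (uni <= hi), out, np.nan)
        return out

    def to_csv(self, path) -> None:
        """Export as two-column CSV (t1_ms, uni)."""
        import pandas as pd

        pd.DataFrame({"t1_ms": self.t1_grid, "uni": self.uni_grid}).to_csv(
            path, index=False
        )


@dataclass
class QuantMap:
    """A quantitative 3D map (ms); unestimable voxels are NaN, never clamped."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7)
    kind: str = "T1"

    def __post_init__(self) -> None:
        if self.kind not in ("T1", "T2star"):
            raise ValueError("kind must be 'T1' or 'T2star'")
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite <= 0).any():
            raise ValueError("finite map values must be positive")


def _block_operator(n: int, cos_fa: float, e1: np.ndarray):
    """Affine map (a, b) of mz across one GRE block of n excitations.

    Each excitation tips mz by the flip angle (mz -> mz*cos_fa) and is
    followed by T1 recovery over one intra-block TR (factor e1), so one
    unit is mz -> mz*cos_fa*e1 + (1 - e1); the n-fold composition has the
    closed geometric-series form below.
    """
    q = cos_fa * e1
    qn = q**n
    # (1 - e1) * (1 - q^n) / (1 - q); q < 1 always for fa in (0, 90)
    b = (1.0 - e1) * (1.0 - qn) / (1.0 - q)
    return qn, b


def _relax(t: float, T1: np.ndarray):
    e = np.exp(-t / T1)
    return e, 1.0 - e


def simulate_mp2rage_signals(T1, params: AcquisitionParams):
    """Steady-state GRE block signals (S1, S2) for tissue with given T1 (ms).

    Returns the longitudinal-magnetization-derived signal amplitudes at the
    k-space centers of the two readout blocks, normalized to unit proton
    density (a common positive scale factor cancels in the UNI contrast).
    Vectorized over ``T1``.
    """
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0):
        raise ValueError("T1 must be positive")
    ta, tb, tc = params.gaps
    c1 = np.cos(np.deg2rad(params.FA1))
    c2 = np.cos(np.deg2rad(params.FA2))
    e1a = np.exp(-params.TR_gre1 / T1)
    e1b = np.exp(-params.TR_gre2 / T1)
    n = params.n_exc

    inv_factor = 1.0 - 2.0 * params.inv_eff
    # compose affine maps mz -> a*mz + b over one full sequence repetition,
    # starting just before the inversion pulse
    ops = []
    ops.append((inv_factor * np.ones_like(T1), np.zeros_like(T1)))
    ops.append(_relax(ta, T1))
    ops.append(_block_operator(n, c1, e1a))
    ops.append(_relax(tb, T1))
    ops.append(_block_operator(n, c2, e1b))
    ops.append(_relax(tc, T1))
    a_tot = np.ones_like(T1)
    b_tot = np.zeros_like(T1)
    for a, b in ops:
        a_tot = a * a_tot
        b_tot = a * b_tot + b
    if np.any(np.abs(a_tot) >= 1.0):
        raise InvalidParameterError(
            "no periodic steady state: |cumulative relaxation factor| >= 1"
        )
    mz = b_tot / (1.0 - a_tot)  # steady state just before inversion

    half = n // 2
    # through inversion, gap TA, and half of block 1 -> mz before the
    # center excitation of block 1
    mz1 = inv_factor * mz
    e, r = _relax(ta, T1)
    mz1 = e * mz1 + r
    a, b = _block_operator(half, c1, e1a)
    mz1 = a * mz1 + b
    s1 = np.sin(np.deg2rad(params.FA1)) * mz1

    # finish block 1, gap TB, half of block 2
    a, b = _block_operator(n - half, c1, e1a)
    mz2 = a * mz1 + b
    e, r = _relax(tb, T1)
    mz2 = e * mz2 + r
    a, b = _block_operator(half, c2, e1b)
    mz2 = a * mz2 + b
    s2 = np.sin(np.deg2rad(params.FA2)) * mz2
    return s1, s2


def uni_contrast(S1, S2):
    """Combined MP2RAGE contrast S1*S2 / (S1^2 + S2^2), bounded in [-0.5, 0.5].

    Invariant to any common positive rescaling of (S1, S2); scalar inputs
    with S1 = S2 = 0 raise :class:`UndefinedContrastError`, array inputs
    yield NaN at such voxels.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    denom = S1**2 + S2**2
    if denom.ndim == 0:
        if denom == 0:
            raise UndefinedContrastError("S1 = S2 = 0")
        return float(S1 * S2 / denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, S1 * S2 / denom, np.nan)
    return out


def build_t1_lookup(
    params: AcquisitionParams,
    t1_min: float = 500.0,
    t1_max: float = 5000.0,
    step: float = 1.0,
) -> LookupTable:
    """Tabulate UNI over a T1 grid and locate the monotone inversion branch.

    The stored ``valid_range`` is the largest strictly monotone run of the
    tabulated UNI curve that contains (or is nearest to) the cortical T1
    regime at 7T (1500-2500 ms).
    """
    if not (0 < t1_min < t1_max):
        raise ValueError("require 0 < t1_min < t1_max")
    if step <= 0 or step > (t1_max - t1_min):
        raise ResolutionError("grid step exceeds the requested T1 range")
    t1 = np.arange(t1_min, t1_max + 0.5 * step, step)
    if t1.size < 3:
        raise ResolutionError("grid too coarse: need at least 3 nodes")
    s1, s2 = simulate_mp2rage_signals(t1, params)
    uni = uni_contrast(s1, s2)

    d = np.diff(uni)
    if np.all(d == 0):
        raise ResolutionError("UNI curve is flat on this grid")
    sign = np.sign(d)
    # maximal runs of strictly monotone (constant-sign, nonzero) differences
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(sign) + 1):
        if i == len(sign) or sign[i] != sign[start] or sign[i] == 0:
            if sign[start] != 0:
                runs.append((start, i))  # uni[start .. i] monotone, inclusive
            start = i
    if not runs:
        raise ResolutionError("no strictly monotone branch found")

    def run_score(run):
        lo, hi = t1[run[0]], t1[run[1]]
        overlap = max(0.0, min(hi, 2500.0) - max(lo, 1500.0))
        return (overlap, hi - lo)

    lo_i, hi_i = max(runs, key=run_score)
    return LookupTable(
        t1_grid=t1,
        uni_grid=uni,
        valid_range=(float(t1[lo_i]), float(t1[hi_i])),
        _lo=lo_i,
        _hi=hi_i,
    )


def estimate_t1_map(
    uni_volume: np.ndarray,
    lut: LookupTable,
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7),
) -> QuantMap:
    """Invert a UNI volume to a T1 map by linear interpolation in the lookup.

    Voxels whose UNI falls outside the monotone branch (or is non-finite)
    are flagged missing (NaN).
    """
    uni = np.asarray(uni_volume, dtype=float)
    t1 = lut.invert(uni)
    t1 = np.where(np.isfinite(uni), t1, np.nan)
    return QuantMap(values=t1, voxel_size=voxel_size, kind="T1")


def simulate_multiecho_decay(S0, T2star, TEs: Sequence[float]):
    """Monoexponential multi-echo signals s_k = S0 * exp(-TE_k / T2star)."""
    S0 = np.asarray(S0, dtype=float)
    T2star = np.asarray(T2star, dtype=float)
    if np.any(S0 <= 0) or np.any(T2star <= 0):
        raise ValueError("S0 and T2star must be positive")
    tes = np.asarray(TEs, dtype=float)
    return S0[..., None] * np.exp(-tes / T2star[..., None])


def _loglinear_t2star(echoes: np.ndarray, tes: np.ndarray):
    """Closed-form log-linear OLS fit; returns (S0, R2*) per voxel.

    ``echoes`` has shape (..., n_echoes); assumes all echoes positive.
    """
    y = np.log(echoes)
    x = tes - tes.mean()
    sxx = float(np.sum(x * x))
    slope = np.tensordot(y, x, axes=([-1], [0])) / sxx
    intercept = y.mean(axis=-1) - slope * tes.mean()
    return np.exp(intercept), -slope


def estimate_t2star_map(
    echo_volumes: Sequence[np.ndarray],
    TEs: Sequence[float],
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 0.7),
    max_iter: int = 50,
    tol: float = 1e-10,
) -> QuantMap:
    """Per-voxel monoexponential T2* fit over multi-echo magnitude volumes.

    A log-linear ordinary-least-squares solution initializes a damped
    Gauss-Newton refinement of the unweighted nonlinear least-squares
    problem min ||s_k - S0 exp(-TE_k R2)||^2 (vectorized over voxels).
    Voxels with any non-positive echo, or a non-decaying log-linear fit,
    are flagged missing.
    """
    tes = np.asarray(TEs, dtype=float)
    if tes.size < 3:
        raise ValueError("need at least 3 echoes")
    echoes = np.stack([np.asarray(v, dtype=float) for v in echo_volumes], axis=-1)
    if echoes.shape[-1] != tes.size:
        raise ValueError("number of echo volumes must match TEs")

    valid = np.all(np.isfinite(echoes) & (echoes > 0), axis=-1)
    safe = np.where(valid[..., None], echoes, 1.0)
    s0, r2 = _loglinear_t2star(safe, tes)
    valid &= r2 > 0
    r2 = np.where(valid, r2, 1.0 / 25.0)
    s0 = np.where(valid, s0, 1.0)

    # damped Gauss-Newton on (S0, R2): residual r_k = s_k - S0 exp(-TE_k R2)
    lam = 0.0
    for _ in range(max_iter):
        e = np.exp(-tes * r2[..., None])
        resid = safe - s0[..., None] * e
        j0 = e  # d model / d S0
        j1 = -s0[..., None] * tes * e  # d model / d R2
        a00 = np.sum(j0 * j0, axis=-1)
        a01 = np.sum(j0 * j1, axis=-1)
        a11 = np.sum(j1 * j1, axis=-1) + lam
        g0 = np.sum(j0 * resid, axis=-1)
        g1 = np.sum(j1 * resid, axis=-1)
        det = a00 * a11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1.0, det)
        d_s0 = (a11 * g0 - a01 * g1) / det
        d_r2 = (a00 * g1 - a01 * g0) / det
        # keep parameters in the physical region
        step_scale = np.ones_like(r2)
        bad = r2 + d_r2 <= 0
        step_scale = np.where(bad, 0.5 * r2 / np.maximum(-d_r2, 1e-300), step_scale)
        bad = s0 + d_s0 <= 0
        step_scale = np.minimum(
            step_scale,
            np.where(bad, 0.5 * s0 / np.maximum(-d_s0, 1e-300), 1.0),
        )
        s0 = s0 + step_scale * d_s0
        r2 = r2 + step_scale * d_r2
        if np.max(np.abs(step_scale * d_r2) / r2, initial=0.0) < tol:
            break

    t2s = np.where(valid & (r2 > 0), 1.0 / r2, np.nan)
    return QuantMap(values=t2s, voxel_size=voxel_size, kind="T2star")
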