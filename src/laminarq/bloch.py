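"""Brute-force longitudinal Bloch time-stepping simulator.

A deliberately simple event-by-event simulation of the MP2RAGEME
longitudinal magnetization used to validate the closed-form steady-state
solution in :mod:`laminarq.mp2rageme`: every excitation is applied
individually, free recovery is integrated in small time steps, and the
periodic steady state is reached by iterating whole sequence repetitions
from thermal equilibrium instead of solving a fixed point.
"""

from __future__ import annotations

import math

from .mp2rageme import AcquisitionParams

__all__ = ["bloch_simulate_signals"]


def _step_relax(mz: float, t: float, T1: float, dt_max: float) -> float:
    """Relax mz toward equilibrium over duration t in steps of <= dt_max."""
    remaining = t
    while remaining > 1e-12:
        dt = min(dt_max, remaining)
        e = math.exp(-dt / T1)
        mz = mz * e + (1.0 - e)
        remaining -= dt
    return mz


def bloch_simulate_signals(
    T1: float,
    params: AcquisitionParams,
    n_reps: int = 5,
    dt_max: float = 1.0,
) -> tuple[float, float]:
    """Simulate (S1, S2) by explicit time stepping over ``n_reps`` repetitions.

    Signal convention matches the analytic model: sin(FA) times the
    longitudinal magnetization just before the k-space-center excitation
    (excitation ``n_exc // 2``, 0-based) of each block.
    """
    if T1 <= 0:
        raise ValueError("T1 must be positive")
    ta, tb, tc = params.gaps
    c1 = math.cos(math.radians(params.FA1))
    c2 = math.cos(math.radians(params.FA2))
    s1f = math.sin(math.radians(params.FA1))
    s2f = math.sin(math.radians(params.FA2))
    center = params.n_exc // 2

    inv_factor = 1.0 - 2.0 * params.inv_eff
    mz = 1.0
    s1 = s2 = float("nan")
    for _ in range(n_reps):
        mz = inv_factor * mz
        mz = _step_relax(mz, ta, T1, dt_max)
        for k in range(params.n_exc):
            if k == center:
                s1 = s1f * mz
            mz = mz * c1
            mz = _step_relax(mz, params.TR_gre1, T1, dt_max)
        mz = _step_relax(mz, tb, T1, dt_max)
        for k in range(params.n_exc):
            if k == center:
                s2 = s2f * mz
            mz = mz * c2
            mz = _step_relax(mz, params.TR_gre2, T1, dt_max)
        mz = _step_relax(mz, tc, T1, dt_max)
    return s1, s2
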