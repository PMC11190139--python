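"""Estimate T1 and T2* from simulated MP2RAGEME signals.

Forward-simulates the two gradient-echo block signals for a known tissue
T1, combines them into the bias-free UNI contrast, and inverts UNI back to
T1 through a lookup table; then fits the multi-echo decay for T2*.  The
printed numbers show that both estimators recover the simulated ground
truth, including under measurement noise.
"""

import numpy as np

from laminarq import (
    AcquisitionParams,
    build_t1_lookup,
    estimate_t1_map,
    estimate_t2star_map,
    simulate_mp2rage_signals,
    simulate_multiecho_decay,
    uni_contrast,
)

params = AcquisitionParams()  # 7T protocol: TI = 670/3675.4 ms, FA = 4 deg
print(f"free recovery gaps (TA, TB, TC) = {params.gaps} ms")

t1_true = 1800.0
s1, s2 = simulate_mp2rage_signals(t1_true, params)
uni = uni_contrast(s1, s2)
print(f"T1 = {t1_true:.0f} ms -> S1 = {s1:+.5f}, S2 = {s2:+.5f}, "
      f"UNI = {uni:+.4f}")

lut = build_t1_lookup(params)  # 500-5000 ms grid, 1 ms step
print(f"lookup monotone branch: {lut.valid_range[0]:.0f}-"
      f"{lut.valid_range[1]:.0f} ms")

# noisy voxels: 1% Gaussian noise on each block signal
rng = np.random.default_rng(0)
n = 5000
uni_noisy = uni_contrast(
    s1 + rng.normal(0, 0.01 * abs(s1), n),
    s2 + rng.normal(0, 0.01 * abs(s2), n),
)
t1_map = estimate_t1_map(uni_noisy, lut)
print(f"recovered T1 (1% noise, {n} voxels): median = "
      f"{np.nanmedian(t1_map.values):.1f} ms, "
      f"IQR = {np.nanpercentile(t1_map.values, 75) - np.nanpercentile(t1_map.values, 25):.1f} ms")

# T2* from the four echoes of the second readout
t2s_true, s0 = 28.0, 100.0
echoes = simulate_multiecho_decay(np.full(n, s0), np.full(n, t2s_true),
                                  params.TEs)
echoes += rng.normal(0, 0.02 * s0, echoes.shape)
t2s_map = estimate_t2star_map([echoes[:, k] for k in range(4)], params.TEs)
print(f"recovered T2* (2% noise): median = "
      f"{np.nanmedian(t2s_map.values):.2f} ms (truth {t2s_true} ms)")
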