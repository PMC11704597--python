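"""JIT-compiled inner loop of the record-level particle filter.

Same mathematics as the array path in :mod:`o2index.filtering` (one OU
propagation, exogenous cardiac-output drive, Fick closure, Gaussian
reweighting, systematic resampling with a Liu-West shrinkage kernel per grid
step), specialized with explicit loops so a full multi-hour record filters
in tens of milliseconds. All randomness is pre-drawn by the caller's
Generator and passed in as arrays, so the kernel is deterministic and shares
the run's seed stream. The two engines are cross-checked in the test suite.

Ensemble rows: 0 = VO2, 1 = Hgb, 2 = SaO2, 3 = k_sv, 4 = CO,
5 = per-particle VO2 baseline attractor.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["filter_chunk"]

R = 6  # ensemble rows


@njit(cache=False)
def filter_chunk(
    X,            # (6, N) ensemble — updated in place
    w,            # (N,) weights — updated in place
    svo2,         # (N,) derived venous saturation — updated in place
    mu,           # (6,) global OU attractors (row 0 unused: VO2 uses row 5)
    phi,          # (6,) per-step decay factors
    q,            # (6,) per-step innovation SDs
    tf_arr,       # (G,) temperature multiplier on the VO2 baseline
    co_gain,      # (G,) CO per unit k_sv (NaN where drivers missing)
    spo2_raw,     # (G,) observations, NaN = absent
    svo2c_raw,
    ci_co_raw,    # continuous CI already converted to CO units
    sd_spo2,
    sd_svo2c,
    sd_ci_co,
    obs_step,     # (M,) aperiodic observations: grid step, ...
    obs_row,      # (M,) ensemble row (-1 = derived SvO2 in %)
    obs_y,
    obs_sd,
    gated,        # (G,) bool: report the index here
    i0,           # first grid step of this chunk (inclusive)
    i1,           # last grid step of this chunk (exclusive)
    thr_frac,     # SvO2 threshold as a fraction
    cap10,        # 10 * Hufner capacity
    ess_min,
    bandwidth,    # Liu-West shrinkage kernel bandwidth h
    z_prop,       # (i1-i0, 6*N) propagation noise
    z_jit,        # (P, 6*N) resampling kernel noise pool (wraps around)
    u_res,        # (i1-i0,) systematic-resampling offsets
    jptr,         # cursor into the jitter pool
    optr,         # aperiodic observation cursor
    values,       # (G,) out: index trace
    mean_svo2,    # (G,) out: posterior-mean SvO2 in %
    mean_vo2,     # (G,) out: posterior-mean VO2, mL/min
    mean_co,      # (G,) out: posterior-mean CO, L/min
):
    N = w.size
    logl = np.empty(N)
    Xn = np.empty((R, N))
    mean_shift = np.empty(R)
    kern_sd = np.empty(R)
    M = obs_step.size
    while optr < M and obs_step[optr] < i0:
        optr += 1
    n_skipped = 0

    for i in range(i0, i1):
        c = i - i0
        for r in range(1, R):
            m = mu[r]
            ph = phi[r]
            qq = q[r]
            base = r * N
            for k in range(N):
                X[r, k] = m + ph * (X[r, k] - m) + qq * z_prop[c, base + k]
        # VO2 reverts to each particle's own temperature-scaled baseline
        tf = tf_arr[i]
        ph0 = phi[0]
        q0 = q[0]
        for k in range(N):
            tgt = X[5, k] * tf
            X[0, k] = tgt + ph0 * (X[0, k] - tgt) + q0 * z_prop[c, k]
        gain = co_gain[i]
        use_gain = gain == gain  # not NaN
        for k in range(N):
            if X[0, k] < 0.0:
                X[0, k] = 0.0
            if X[1, k] < 1e-6:
                X[1, k] = 1e-6
            if X[2, k] < 0.0:
                X[2, k] = 0.0
            elif X[2, k] > 1.0:
                X[2, k] = 1.0
            if X[3, k] < 1e-9:
                X[3, k] = 1e-9
            if use_gain:
                X[4, k] = X[3, k] * gain
            if X[4, k] < 1e-6:
                X[4, k] = 1e-6
            if X[5, k] < 1.0:
                X[5, k] = 1.0
            sv = X[2, k] - X[0, k] / (X[4, k] * cap10 * X[1, k])
            if sv < 0.0:
                sv = 0.0
            elif sv > X[2, k]:
                sv = X[2, k]
            svo2[k] = sv

        any_obs = False
        y = spo2_raw[i]
        if y == y:
            inv = 1.0 / sd_spo2
            for k in range(N):
                d = (X[2, k] * 100.0 - y) * inv
                logl[k] = d * d
            any_obs = True
        else:
            for k in range(N):
                logl[k] = 0.0
        y = svo2c_raw[i]
        if y == y:
            inv = 1.0 / sd_svo2c
            for k in range(N):
                d = (svo2[k] * 100.0 - y) * inv
                logl[k] += d * d
            any_obs = True
        y = ci_co_raw[i]
        if y == y:
            inv = 1.0 / sd_ci_co
            for k in range(N):
                d = (X[4, k] - y) * inv
                logl[k] += d * d
            any_obs = True
        while optr < M and obs_step[optr] == i:
            row = obs_row[optr]
            y = obs_y[optr]
            inv = 1.0 / obs_sd[optr]
            if row == -1:
                for k in range(N):
                    d = (svo2[k] * 100.0 - y) * inv
                    logl[k] += d * d
            elif row == 2:  # SaO2 observed in percent
                for k in range(N):
                    d = (X[2, k] * 100.0 - y) * inv
                    logl[k] += d * d
            else:
                for k in range(N):
                    d = (X[row, k] - y) * inv
                    logl[k] += d * d
            any_obs = True
            optr += 1

        if any_obs:
            lmin = logl[0]
            for k in range(1, N):
                if logl[k] < lmin:
                    lmin = logl[k]
            s = 0.0
            for k in range(N):
                lw = w[k] * math.exp(-0.5 * (logl[k] - lmin))
                logl[k] = lw  # reuse buffer for unnormalized weights
                s += lw
            if s > 0.0 and math.isfinite(s):
                inv = 1.0 / s
                for k in range(N):
                    w[k] = logl[k] * inv
            else:
                n_skipped += 1
            ss = 0.0
            for k in range(N):
                ss += w[k] * w[k]
            if 1.0 / ss < ess_min:
                # systematic resampling + Liu-West shrinkage kernel:
                # variance-preserving, so ensemble diversity of slow states
                # survives frequent resampling without artificial diffusion
                a = math.sqrt(1.0 - bandwidth * bandwidth)
                for r in range(R):
                    mr = 0.0
                    m2 = 0.0
                    for k in range(N):
                        mr += w[k] * X[r, k]
                        m2 += w[k] * X[r, k] * X[r, k]
                    var = m2 - mr * mr
                    sdr = math.sqrt(var) if var > 0.0 else 0.0
                    mean_shift[r] = (1.0 - a) * mr
                    kern_sd[r] = bandwidth * sdr
                u = u_res[c]
                zr = jptr % z_jit.shape[0]
                jptr += 1
                j = 0
                cum = w[0]
                for k in range(N):
                    p = (u + k) / N
                    while cum < p and j < N - 1:
                        j += 1
                        cum += w[j]
                    for r in range(R):
                        Xn[r, k] = a * X[r, j] + mean_shift[r] + kern_sd[r] * z_jit[zr, r * N + k]
                for k in range(N):
                    for r in range(R):
                        X[r, k] = Xn[r, k]
                    if X[0, k] < 0.0:
                        X[0, k] = 0.0
                    if X[1, k] < 1e-6:
                        X[1, k] = 1e-6
                    if X[2, k] > 1.0:
                        X[2, k] = 1.0
                    if X[3, k] < 1e-9:
                        X[3, k] = 1e-9
                    if X[4, k] < 1e-6:
                        X[4, k] = 1e-6
                    if X[5, k] < 1.0:
                        X[5, k] = 1.0
                    sv = X[2, k] - X[0, k] / (X[4, k] * cap10 * X[1, k])
                    if sv < 0.0:
                        sv = 0.0
                    elif sv > X[2, k]:
                        sv = X[2, k]
                    svo2[k] = sv
                    w[k] = 1.0 / N

        if gated[i]:
            pv = 0.0
            mv = 0.0
            vv = 0.0
            cv = 0.0
            for k in range(N):
                if svo2[k] <= thr_frac:
                    pv += w[k]
                mv += w[k] * svo2[k]
                vv += w[k] * X[0, k]
                cv += w[k] * X[4, k]
            values[i] = pv
            mean_svo2[i] = 100.0 * mv
            mean_vo2[i] = vv
            mean_co[i] = cv
    return optr, jptr, n_skipped
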