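"""Numba kernels: NpT Metropolis Monte Carlo for single-site LJ fluids.

This is the accelerated path used for the methane-scale campaigns (hundreds of
molecules, tens of thousands of MC cycles).  The general engine in
``sampler_mc`` is the reference implementation; the two are cross-checked
statistically in the test suite.  Conventions match the general engine:
volume moves uniform in ln V with the (N+1) Jacobian, hard inner cutoff at
1 Å, cutoff treatments hard/shifted/tail, density accumulated after every
attempted move.

Performance notes: coordinates are kept wrapped in [0, L) as separate x/y/z
arrays; pair loops are written branch-free (conditional-select accumulation,
``error_model='numpy'``) so LLVM can vectorize them; volume-move energies
reuse the unscaled minimum-image distances, since a uniform coordinate/box
rescaling only multiplies every pair distance by the scale factor.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: lrc_mode encoding for kernels
MODE_HARD, MODE_SHIFTED, MODE_TAIL = 0, 1, 2

R_MIN2 = 1.0  # Å^2, hard inner cutoff squared

OVERLAP = 1.0e300


@njit(cache=True, fastmath=True, error_model="numpy")
def _total_energy(x, y, z, L, scale, rc2, sigma2, eps4, ushift):
    """Total pair energy of the configuration scaled by ``scale`` (box
    ``scale * L``); OVERLAP when any pair is inside the hard core."""
    n = x.shape[0]
    invL = 1.0 / L
    s2 = scale * scale
    u = 0.0
    n_over = 0.0
    for i in range(n - 1):
        xi = x[i]
        yi = y[i]
        zi = z[i]
        for j in range(i + 1, n):
            dx = x[j] - xi
            dx -= L * np.floor(dx * invL + 0.5)
            dy = y[j] - yi
            dy -= L * np.floor(dy * invL + 0.5)
            dz = z[j] - zi
            dz -= L * np.floor(dz * invL + 0.5)
            r2 = s2 * (dx * dx + dy * dy + dz * dz)
            inv = sigma2 / r2
            s6 = inv * inv * inv
            e = eps4 * (s6 * s6 - s6) - ushift
            u += e if r2 <= rc2 else 0.0
            n_over += 1.0 if r2 < R_MIN2 else 0.0
    if n_over > 0.0:
        return OVERLAP
    return u


@njit(cache=True, fastmath=True, error_model="numpy")
def _energy_one(x, y, z, i, xi, yi, zi, L, rc2, sigma2, eps4, ushift):
    """Interaction energy of a site at (xi, yi, zi) with all sites except i;
    OVERLAP on hard-core contact."""
    n = x.shape[0]
    invL = 1.0 / L
    u = 0.0
    n_over = 0.0
    for j in range(i):
        dx = x[j] - xi
        dx -= L * np.floor(dx * invL + 0.5)
        dy = y[j] - yi
        dy -= L * np.floor(dy * invL + 0.5)
        dz = z[j] - zi
        dz -= L * np.floor(dz * invL + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        inv = sigma2 / r2
        s6 = inv * inv * inv
        e = eps4 * (s6 * s6 - s6) - ushift
        u += e if r2 <= rc2 else 0.0
        n_over += 1.0 if r2 < R_MIN2 else 0.0
    for j in range(i + 1, n):
        dx = x[j] - xi
        dx -= L * np.floor(dx * invL + 0.5)
        dy = y[j] - yi
        dy -= L * np.floor(dy * invL + 0.5)
        dz = z[j] - zi
        dz -= L * np.floor(dz * invL + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        inv = sigma2 / r2
        s6 = inv * inv * inv
        e = eps4 * (s6 * s6 - s6) - ushift
        u += e if r2 <= rc2 else 0.0
        n_over += 1.0 if r2 < R_MIN2 else 0.0
    if n_over > 0.0:
        return OVERLAP
    return u


def lj_energy_total(pos, L, rc2, sigma2, eps4, ushift):
    """All-pairs LJ energy of an (n, 3) coordinate array (wrapper)."""
    x = np.ascontiguousarray(pos[:, 0])
    y = np.ascontiguousarray(pos[:, 1])
    z = np.ascontiguousarray(pos[:, 2])
    return _total_energy(x, y, z, L, 1.0, rc2, sigma2, eps4, ushift)


@njit(cache=True, fastmath=True, error_model="numpy")
def npt_lj_stage(pos, L, beta, p_e, n_mcc, sample_every, sigma, eps, rc,
                 mode, tail_coef, d_trans, d_lnv, p_vol, adapt, target_acc,
                 adapt_interval, rho_factor, seed):
    """One MC stage; returns samples, counters, accumulators, final state.

    p_e: external pressure in kJ/mol/Å^3 (volume moves disabled when
    ``p_vol`` is 0 -> NVT).  tail_coef: U_tail = tail_coef / V (0 unless
    tail mode).  Density rho = rho_factor / V is accumulated after every
    attempted move.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    rc2 = rc * rc
    sigma2 = sigma * sigma
    eps4 = 4.0 * eps
    ushift = 0.0
    if mode == MODE_SHIFTED:
        xc6 = (sigma2 / rc2) ** 3
        ushift = eps4 * (xc6 * xc6 - xc6)
    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    for i in range(n):
        x[i] = pos[i, 0] - L * np.floor(pos[i, 0] / L)
        y[i] = pos[i, 1] - L * np.floor(pos[i, 1] / L)
        z[i] = pos[i, 2] - L * np.floor(pos[i, 2] / L)

    u_pair = _total_energy(x, y, z, L, 1.0, rc2, sigma2, eps4, ushift)
    n_samples = n_mcc // sample_every
    samp_v = np.empty(n_samples)
    samp_u = np.empty(n_samples)
    acc_rho = 0.0
    acc_n = 0.0
    att_t = 0
    acc_t = 0
    att_v = 0
    acc_v = 0
    win_att_t = 0
    win_acc_t = 0
    win_att_v = 0
    win_acc_v = 0
    isamp = 0
    for mcc in range(n_mcc):
        for _ in range(n):
            if p_vol > 0.0 and np.random.random() < p_vol:
                att_v += 1
                win_att_v += 1
                V = L * L * L
                dln = (2.0 * np.random.random() - 1.0) * d_lnv
                Vn = V * np.exp(dln)
                Ln = Vn ** (1.0 / 3.0)
                if Ln >= 2.0 * rc:
                    s = Ln / L
                    u_new = _total_energy(x, y, z, L, s, rc2, sigma2, eps4,
                                          ushift)
                    if u_new < OVERLAP:
                        du = u_new - u_pair
                        if mode == MODE_TAIL:
                            du += tail_coef / Vn - tail_coef / V
                        arg = -beta * (du + p_e * (Vn - V)) + (n + 1) * dln
                        if arg > 0.0 or np.random.random() < np.exp(arg):
                            for i in range(n):
                                x[i] *= s
                                y[i] *= s
                                z[i] *= s
                            L = Ln
                            u_pair = u_new
                            acc_v += 1
                            win_acc_v += 1
            else:
                att_t += 1
                win_att_t += 1
                i = np.random.randint(n)
                xn = x[i] + (2.0 * np.random.random() - 1.0) * d_trans
                yn = y[i] + (2.0 * np.random.random() - 1.0) * d_trans
                zn = z[i] + (2.0 * np.random.random() - 1.0) * d_trans
                xn -= L * np.floor(xn / L)
                yn -= L * np.floor(yn / L)
                zn -= L * np.floor(zn / L)
                u_new = _energy_one(x, y, z, i, xn, yn, zn, L, rc2, sigma2,
                                    eps4, ushift)
                if u_new < OVERLAP:
                    u_old = _energy_one(x, y, z, i, x[i], y[i], z[i], L, rc2,
                                        sigma2, eps4, ushift)
                    du = u_new - u_old
                    if du <= 0.0 or np.random.random() < np.exp(-beta * du):
                        x[i] = xn
                        y[i] = yn
                        z[i] = zn
                        u_pair += du
                        acc_t += 1
                        win_acc_t += 1
            acc_rho += rho_factor / (L * L * L)
            acc_n += 1.0
        if adapt and (mcc + 1) % adapt_interval == 0:
            if win_att_t > 0:
                f = (win_acc_t / win_att_t) / target_acc
                if f < 0.5:
                    f = 0.5
                elif f > 2.0:
                    f = 2.0
                d_trans *= f
                if d_trans > L / 4.0:
                    d_trans = L / 4.0
                if d_trans < 0.001:
                    d_trans = 0.001
            if win_att_v > 0:
                f = (win_acc_v / win_att_v) / target_acc
                if f < 0.5:
                    f = 0.5
                elif f > 2.0:
                    f = 2.0
                d_lnv *= f
                if d_lnv > 0.5:
                    d_lnv = 0.5
                if d_lnv < 1e-5:
                    d_lnv = 1e-5
            win_att_t = 0
            win_acc_t = 0
            win_att_v = 0
            win_acc_v = 0
        if (mcc + 1) % sample_every == 0 and isamp < n_samples:
            samp_v[isamp] = L * L * L
            u_tot = u_pair
            if mode == MODE_TAIL:
                u_tot += tail_coef / (L * L * L)
            samp_u[isamp] = u_tot
            isamp += 1
    for i in range(n):
        pos[i, 0] = x[i]
        pos[i, 1] = y[i]
        pos[i, 2] = z[i]
    return (pos, L, u_pair, samp_v[:isamp], samp_u[:isamp], acc_rho, acc_n,
            att_t, acc_t, att_v, acc_v, d_trans, d_lnv)
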