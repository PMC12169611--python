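"""Minimal NpT molecular dynamics for single-site LJ/WCA fluids.

The purpose of this engine is to expose the MD-side cutoff physics that a
Metropolis Monte Carlo sampler is immune to: with a hard-truncated potential
the force is discontinuous at r_cut, the integrator never sees the energy
jump, and hard-truncated and shifted-potential runs produce *identical*
trajectories — whereas MC accounts for the energy jump in its acceptance rule.

Integration: velocity Verlet; Nosé–Hoover thermostat (single chain) and an
MTK-style isotropic barostat, both with damping given in time steps;
3N-3 degrees of freedom (center-of-mass momentum is zeroed at start and
conserved).  Deliberately restricted to single-site potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from numba import njit

from .configio import Snapshot, build_lattice_config
from .constants import DENSITY_FACTOR, KE_FACTOR, KJMOL_A3_TO_KPA, R_KJ
from .models import StatePoint, builtin_forcefields, builtin_models
from .sampler_mc import TrajectoryRecord

__all__ = [
    "MDSettings",
    "WCAPotential",
    "run_md_npt",
    "md_mc_discrepancy",
    "timestep_sensitivity",
]

FORCE_MODES = ("hard", "shifted", "tail", "wca")


@dataclass(frozen=True)
class WCAPotential:
    """Purely repulsive LJ truncated and shifted at 2^(1/6) sigma; energy and
    force both vanish at the cutoff."""

    sigma: float
    epsilon: float

    @property
    def r_cut(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma


@dataclass
class MDSettings:
    timestep_fs: float = 2.0
    thermostat_damping: int = 100      # steps
    barostat_damping: int = 1000       # steps
    force_mode: str = "tail"
    dof_convention: str = "3N-3"

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.thermostat_damping < 1 or self.barostat_damping < 1:
            raise ValueError("damping must be at least one step")
        if self.force_mode not in FORCE_MODES:
            raise ValueError(f"force_mode must be one of {FORCE_MODES}")


@njit(cache=True, fastmath=True, error_model="numpy")
def lj_forces(pos, L, rc2, sigma2, eps4, ushift):
    """Truncated-LJ forces; returns (F, U, W) with W = sum r.(-du/dr).

    ``ushift`` is subtracted per in-range pair (shifted/WCA energy); forces
    are identical for hard and shifted treatments by construction.  The pair
    loop is split into a vectorizable distance pass over scratch buffers and
    a sparse force-accumulation pass.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    U = 0.0
    W = 0.0
    invL = 1.0 / L
    bx = np.empty(n)
    by = np.empty(n)
    bz = np.empty(n)
    br = np.empty(n)
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        m = n - 1 - i
        for jj in range(m):
            j = i + 1 + jj
            dx = pos[j, 0] - xi
            dx -= L * np.floor(dx * invL + 0.5)
            dy = pos[j, 1] - yi
            dy -= L * np.floor(dy * invL + 0.5)
            dz = pos[j, 2] - zi
            dz -= L * np.floor(dz * invL + 0.5)
            bx[jj] = dx
            by[jj] = dy
            bz[jj] = dz
            br[jj] = dx * dx + dy * dy + dz * dz
        for jj in range(m):
            r2 = br[jj]
            if r2 <= rc2:
                j = i + 1 + jj
                s6 = (sigma2 / r2) ** 3
                U += eps4 * (s6 * s6 - s6) - ushift
                fr = eps4 * (12.0 * s6 * s6 - 6.0 * s6) / r2   # (-du/dr)/r
                W += fr * r2
                F[i, 0] -= fr * bx[jj]
                F[i, 1] -= fr * by[jj]
                F[i, 2] -= fr * bz[jj]
                F[j, 0] += fr * bx[jj]
                F[j, 1] += fr * by[jj]
                F[j, 2] += fr * bz[jj]
    return F, U, W


@njit(cache=True, fastmath=True, error_model="numpy")
def md_stage(pos, vel, L, mass_red, dt, n_steps, kbt, p_e, tau_t, tau_p,
             rc2, sigma2, eps4, ushift, tail_u_coef, tail_w_coef,
             use_thermostat, use_barostat, sample_every):
    """Velocity-Verlet NVE/NVT/NpT stage in internal units.

    mass_red = mass * 0.01 (kJ/mol ps^2/Å^2); p_e in kJ/mol/Å^3.
    tail_u_coef/V and tail_w_coef/V are the energy and virial tail terms.
    Returns samples (V, rho-less volume, T_kin, U, P) and final state; the
    divergence flag is 1 when the energy blew up.
    """
    n = pos.shape[0]
    dof = 3 * n - 3
    Q = dof * kbt * tau_t * tau_t
    Wb = (dof + 3) * kbt * tau_p * tau_p
    xi = 0.0
    v_eps = 0.0
    alpha = 1.0 + 3.0 / dof
    F, U, W = lj_forces(pos, L, rc2, sigma2, eps4, ushift)
    n_samples = n_steps // sample_every
    samp_v = np.empty(n_samples)
    samp_t = np.empty(n_samples)
    samp_u = np.empty(n_samples)
    samp_p = np.empty(n_samples)
    isamp = 0
    diverged = 0
    u0 = abs(U) + dof * kbt + 1.0
    for step in range(n_steps):
        V = L * L * L
        ke2 = 0.0
        for i in range(n):
            ke2 += mass_red * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        # half-step thermostat/barostat
        if use_barostat:
            p_int = (ke2 + W + tail_w_coef / V) / (3.0 * V)
            g_eps = (3.0 * V * (p_int - p_e) + (3.0 / dof) * ke2) / Wb
            v_eps += 0.5 * dt * g_eps
        if use_thermostat:
            xi += 0.5 * dt * (ke2 - dof * kbt) / Q
            scale = np.exp(-0.5 * dt * (xi + (alpha * v_eps if use_barostat else 0.0)))
            for i in range(n):
                vel[i, 0] *= scale
                vel[i, 1] *= scale
                vel[i, 2] *= scale
        elif use_barostat:
            scale = np.exp(-0.5 * dt * alpha * v_eps)
            for i in range(n):
                vel[i, 0] *= scale
                vel[i, 1] *= scale
                vel[i, 2] *= scale
        # half kick
        for i in range(n):
            vel[i, 0] += 0.5 * dt * F[i, 0] / mass_red
            vel[i, 1] += 0.5 * dt * F[i, 1] / mass_red
            vel[i, 2] += 0.5 * dt * F[i, 2] / mass_red
        # drift (+ cell scaling)
        if use_barostat:
            s = np.exp(v_eps * dt)
            L *= s
            for i in range(n):
                pos[i, 0] = pos[i, 0] * s + vel[i, 0] * dt
                pos[i, 1] = pos[i, 1] * s + vel[i, 1] * dt
                pos[i, 2] = pos[i, 2] * s + vel[i, 2] * dt
        else:
            for i in range(n):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
        F, U, W = lj_forces(pos, L, rc2, sigma2, eps4, ushift)
        # second half kick
        for i in range(n):
            vel[i, 0] += 0.5 * dt * F[i, 0] / mass_red
            vel[i, 1] += 0.5 * dt * F[i, 1] / mass_red
            vel[i, 2] += 0.5 * dt * F[i, 2] / mass_red
        ke2 = 0.0
        for i in range(n):
            ke2 += mass_red * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        if use_thermostat:
            if use_barostat:
                scale = np.exp(-0.5 * dt * alpha * v_eps)
                for i in range(n):
                    vel[i, 0] *= scale
                    vel[i, 1] *= scale
                    vel[i, 2] *= scale
                ke2 *= scale * scale
            xi += 0.5 * dt * (ke2 - dof * kbt) / Q
            scale = np.exp(-0.5 * dt * xi)
            for i in range(n):
                vel[i, 0] *= scale
                vel[i, 1] *= scale
                vel[i, 2] *= scale
            ke2 *= scale * scale
        if use_barostat:
            V = L * L * L
            p_int = (ke2 + W + tail_w_coef / V) / (3.0 * V)
            g_eps = (3.0 * V * (p_int - p_e) + (3.0 / dof) * ke2) / Wb
            v_eps += 0.5 * dt * g_eps
        if abs(U) > 1.0e6 * u0 or not np.isfinite(U):
            diverged = 1
            break
        if (step + 1) % sample_every == 0 and isamp < n_samples:
            V = L * L * L
            samp_v[isamp] = V
            samp_t[isamp] = ke2 / (dof * R_KJ_NB)
            samp_u[isamp] = U + tail_u_coef / V
            samp_p[isamp] = (ke2 + W + tail_w_coef / V) / (3.0 * V)
            isamp += 1
    return (pos, vel, L, samp_v[:isamp], samp_t[:isamp], samp_u[:isamp],
            samp_p[:isamp], diverged)


#: numba-visible copy of the gas constant
R_KJ_NB = R_KJ


def _resolve_potential(sp: StatePoint, settings: MDSettings,
                       wca: WCAPotential | None):
    tmpl = builtin_models()[sp.model]
    if tmpl.n_sites != 1:
        raise ValueError("the MD engine supports single-site models only")
    ff = builtin_forcefields()[tmpl.ff_name]
    at = ff.atom_types[tmpl.site_types[0]]
    sigma, eps, mass = at.lj.sigma, at.lj.epsilon, at.mass
    if settings.force_mode == "wca":
        pot = wca or WCAPotential(sigma, eps)
        rc = pot.r_cut
        sigma, eps = pot.sigma, pot.epsilon
        # pair value at the cutoff (= -eps); subtracting it shifts WCA up by +eps
        ushift = 4.0 * eps * ((sigma / rc) ** 12 - (sigma / rc) ** 6)
    else:
        rc = sp.r_cut
        x6 = (sigma / rc) ** 6
        ushift = 4.0 * eps * (x6 * x6 - x6) if settings.force_mode == "shifted" else 0.0
    return sigma, eps, mass, rc, ushift


def run_md_npt(sp: StatePoint, settings: MDSettings | None = None,
               seed: int = 0, n_equil_steps: int = 20000,
               n_prod_steps: int = 50000, sample_every: int = 100,
               snap: Snapshot | None = None, ensemble: str = "npt",
               wca: WCAPotential | None = None,
               label: str = "") -> TrajectoryRecord:
    """Staged MD run (thermalization then production) for one replicate.

    ``ensemble`` may be 'npt', 'nvt', or 'nve' (thermostat/barostat off for
    conservation checks).  Raises on energy divergence with a diagnostic.
    """
    settings = settings or MDSettings()
    sigma, eps, mass, rc, ushift = _resolve_potential(sp, settings, wca)
    snap = snap or build_lattice_config(sp, seed)
    pos = snap.coords.copy()
    L = snap.box
    if L < 2.0 * rc:
        raise ValueError(f"box edge {L:.2f} Å below 2*r_cut = {2 * rc:.2f} Å")
    n = sp.N
    mass_red = mass * KE_FACTOR
    rng = np.random.default_rng(seed)
    vel = rng.normal(scale=math.sqrt(R_KJ * sp.T / mass_red), size=(n, 3))
    vel -= vel.mean(axis=0)
    dt = settings.timestep_fs * 1e-3   # ps
    kbt = R_KJ * sp.T
    p_e = sp.p / KJMOL_A3_TO_KPA
    tail_u = tail_w = 0.0
    if settings.force_mode == "tail":
        x3 = (sigma / rc) ** 3
        x9 = x3**3
        tail_u = (8.0 * math.pi / 3.0) * n**2 * eps * sigma**3 * (x9 / 3.0 - x3)
        # virial tail: 3V p_tail
        tail_w = 16.0 * math.pi * n**2 * eps * sigma**3 * (2.0 * x9 / 3.0 - x3)
    use_t = ensemble in ("nvt", "npt")
    use_b = ensemble == "npt"
    tmpl = builtin_models()[sp.model]
    ffs = builtin_forcefields()[tmpl.ff_name]
    rho_factor = DENSITY_FACTOR * n * mass
    samples = {"mcc": [], "volume": [], "rho": [], "u": []}
    labels: list[str] = []
    tkin_all: list[float] = []
    tkin_prod = []
    offset = 0

    def _stage(name, n_steps):
        nonlocal pos, vel, L, offset
        if n_steps <= 0:
            return
        out = md_stage(pos, vel, L, mass_red, dt, n_steps, kbt, p_e,
                       settings.thermostat_damping * dt,
                       settings.barostat_damping * dt,
                       rc * rc, sigma * sigma, 4.0 * eps, ushift,
                       tail_u, tail_w, use_t, use_b, sample_every)
        pos, vel, L, sv, st, su, sp_, diverged = out
        finite = (np.isfinite(pos).all() and np.isfinite(vel).all()
                  and np.isfinite(su).all() and np.isfinite(st).all())
        if diverged or not finite or (len(st) and st.max() > 100.0 * sp.T):
            raise RuntimeError(
                f"MD energy divergence in stage {name!r} "
                f"(dt = {settings.timestep_fs} fs); reduce the time step")
        k = len(sv)
        samples["mcc"].extend((offset + (np.arange(k) + 1) * sample_every).tolist())
        samples["volume"].extend(sv.tolist())
        samples["rho"].extend((rho_factor / sv).tolist())
        samples["u"].extend(su.tolist())
        labels.extend([name] * k)
        tkin_all.extend(st.tolist())
        if name == "production":
            tkin_prod.extend(st.tolist())
        offset += n_steps

    _stage("equilibration", n_equil_steps)
    _stage("production", n_prod_steps)
    rho_prod = np.array([r for r, l in zip(samples["rho"], labels)
                         if l == "production"])
    rec = TrajectoryRecord(
        model=sp.model, sp=sp, seed=seed,
        mcc=np.array(samples["mcc"]), volume=np.array(samples["volume"]),
        rho=np.array(samples["rho"]), u_total=np.array(samples["u"]),
        stage_labels=labels, counters={},
        prod_acc_rho=float(rho_prod.sum()), prod_acc_n=float(len(rho_prod)),
        final_box=L, final_schedule=None, method="md", label=label)
    rec.kinetic_temperature = (float(np.mean(tkin_prod)) if tkin_prod else
                               float("nan"))
    rec.tkin_series = np.array(tkin_all)
    rec.final_state = (pos, vel, L)
    return rec


def md_mc_discrepancy(sp: StatePoint, r_cut: float, seeds: list[int],
                      md_settings: MDSettings | None = None,
                      mc_plan=None, md_steps: tuple[int, int] = (20000, 50000),
                      ) -> dict:
    """Paired MD (hard-truncated forces + tail) vs MC (tail) density
    comparison: 100 (rho_MD - rho_MC)/rho_MC with propagated 95% CI."""
    from .analysis import replicate_statistics
    from .sampler_mc import run_npt

    sp_rc = dc_replace(sp, r_cut=r_cut)
    md_settings = md_settings or MDSettings(force_mode="tail")
    md_runs = [run_md_npt(sp_rc, md_settings, seed=s,
                          n_equil_steps=md_steps[0], n_prod_steps=md_steps[1])
               for s in seeds]
    mc_runs = [run_npt(sp_rc, seed=s, plan=mc_plan, lrc_mode="tail")
               for s in seeds]
    md_stats = replicate_statistics(md_runs)
    mc_stats = replicate_statistics(mc_runs)
    pct = 100.0 * (md_stats.mean - mc_stats.mean) / mc_stats.mean
    ci = 100.0 / mc_stats.mean * math.hypot(md_stats.ci95, mc_stats.ci95)
    return {"rho_md": md_stats.mean, "rho_mc": mc_stats.mean,
            "pct_difference": pct, "ci95_pct": ci}


def timestep_sensitivity(sp: StatePoint, dts_fs: list[float], seeds: list[int],
                         force_mode: str = "tail",
                         steps_at_dt1: tuple[int, int] = (20000, 50000)):
    """Replicate densities per time step with a statistical-equality flag.

    The simulated physical time is held fixed: step counts scale as 1/dt.
    """
    import pandas as pd

    from .analysis import replicate_statistics

    if len(dts_fs) < 2:
        raise ValueError("need at least two time-step values")
    rows = []
    for dt in dts_fs:
        scale = 1.0 / dt
        settings = MDSettings(timestep_fs=dt, force_mode=force_mode)
        runs = [run_md_npt(sp, settings, seed=s,
                           n_equil_steps=int(steps_at_dt1[0] * scale),
                           n_prod_steps=int(steps_at_dt1[1] * scale))
                for s in seeds]
        stats = replicate_statistics(runs)
        rows.append({"dt_fs": dt, "rho_mean": stats.mean, "ci95": stats.ci95})
    df = pd.DataFrame(rows)
    lo = (df["rho_mean"] - df["ci95"]).max()
    hi = (df["rho_mean"] + df["ci95"]).min()
    df.attrs["statistically_equal"] = bool(lo <= hi)
    return df
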