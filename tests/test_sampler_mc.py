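"""NpT Monte Carlo: acceptance rule, bookkeeping, adaptation, CBMC."""

import math
from dataclasses import replace

import numpy as np
import pytest

from replibench.configio import Snapshot, build_lattice_config
from replibench.constants import DENSITY_FACTOR, KPA_A3_TO_KJMOL, R_KJ
from replibench.energy import dihedral_angle
from replibench.ffparams import AtomType, ForceField, LJParameters
from replibench.models import (
    MoleculeTemplate,
    StatePoint,
    builtin_forcefields,
    builtin_models,
)
from replibench.models import _build_zmat
from replibench.sampler_mc import (
    GeneralNptMC,
    MoveSchedule,
    StagePlan,
    adapt_max_displacements,
    metropolis_probability,
    run_cutoff_scan,
    run_npt,
)


def lj_single_site(sigma=3.73, eps=1.23, rc=6.0, lrc="hard"):
    ff = ForceField(
        name="lj",
        atom_types={"A": AtomType(LJParameters(sigma, eps), 0.0, 16.043)},
        r_cut=rc, lrc_mode=lrc)
    tmpl = {"a": MoleculeTemplate("a", "lj", ["A"], rigidity="point",
                                  reference_coords=np.zeros((1, 3)),
                                  rough_density=375.0)}
    return ff, tmpl


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        assert metropolis_probability(-1.0, 1.0) == 1.0

    def test_detailed_balance_stationarity_on_enumerable_chain(self):
        """Brute-force oracle: on a discrete ring with symmetric +-1 proposals
        and Metropolis acceptance, the Boltzmann distribution is stationary."""
        M = 24
        beta = 1.7
        E = np.sin(2 * np.pi * np.arange(M) / M) * 2.0
        P = np.zeros((M, M))
        for i in range(M):
            for j in ((i - 1) % M, (i + 1) % M):
                P[i, j] = 0.5 * metropolis_probability(E[j] - E[i], beta)
            P[i, i] = 1.0 - P[i].sum()
        pi = np.exp(-beta * E)
        pi /= pi.sum()
        np.testing.assert_allclose(pi @ P, pi, atol=1e-14)
        # and detailed balance itself
        for i in range(M):
            for j in range(M):
                assert pi[i] * P[i, j] == pytest.approx(pi[j] * P[j, i],
                                                        abs=1e-15)

    def test_two_particle_sampling_matches_direct_oracle(self):
        """Empirical check of the whole translation-move chain: the pair
        distance distribution of two LJ particles in a periodic box must match
        direct importance sampling of uniform configurations."""
        ff, tmpl = lj_single_site(rc=6.0)
        sp = StatePoint("a", 2, 160.0, 1000.0, 6.0)
        L = 13.0
        snap = Snapshot(box=L, coords=np.array([[2, 2, 2], [6, 6, 6.0]]),
                        mol_index=np.arange(2), mol_templates=["a", "a"])
        plan = StagePlan(melt_mcc=0, cool_mcc=0, equil_block_mcc=500,
                         max_equil_blocks=1, equil_check_mcc=100,
                         production_mcc=0, sample_interval=1)
        # drive the fast kernel directly through run_npt in NVT-like fashion
        from replibench import mc_fast
        beta = 1.0 / (R_KJ * sp.T)
        out = mc_fast.npt_lj_stage(
            snap.coords.copy(), L, beta, 0.0, 200000, 1, 3.73, 1.23, 6.0,
            mc_fast.MODE_HARD, 0.0, 1.5, 0.0, 0.0, False, 0.4, 100, 1.0, 99)
        # re-run recording distances by chunks
        rng = np.random.default_rng(0)
        pos = snap.coords.copy()
        dists = []
        for chunk in range(1000):
            out = mc_fast.npt_lj_stage(
                pos, L, beta, 0.0, 25, 1, 3.73, 1.23, 6.0,
                mc_fast.MODE_HARD, 0.0, 1.5, 0.0, 0.0, False, 0.4, 100, 1.0,
                int(rng.integers(2**31)))
            pos = out[0]
            d = pos[1] - pos[0]
            d -= L * np.round(d / L)
            dists.append(np.linalg.norm(d))
        dists = np.array(dists)
        # direct oracle: uniform pairs reweighted by the Boltzmann factor
        u1 = rng.random((400000, 3)) * L
        u2 = rng.random((400000, 3)) * L
        d = u2 - u1
        d -= L * np.round(d / L)
        r = np.sqrt((d**2).sum(1))
        x6 = np.where(r > 0.1, (3.73 / r) ** 6, 1e12)
        u = np.where(r <= 6.0, 4 * 1.23 * (x6 * x6 - x6), 0.0)
        u = np.where(r < 1.0, 1e6, u)
        w = np.exp(-beta * u)
        edges = np.linspace(0, L / 2, 8)
        h_chain, _ = np.histogram(dists, bins=edges)
        h_or, _ = np.histogram(r, bins=edges, weights=w)
        p_chain = h_chain / h_chain.sum()
        p_or = h_or / h_or.sum()
        np.testing.assert_allclose(p_chain, p_or, atol=0.06)


class TestIdealGasNpT:
    def test_mean_volume_closed_form(self):
        """Uniform-lnV volume moves with the (N+1) Jacobian sample
        pi(V) ~ V^N exp(-beta p V), whose mean is (N+1) k_B T / p."""
        from replibench import mc_fast
        N, T, p_kpa = 20, 300.0, 500.0
        beta = 1.0 / (R_KJ * T)
        p_e = p_kpa * KPA_A3_TO_KJMOL
        expected_V = (N + 1) / (beta * p_e)
        L0 = expected_V ** (1 / 3)
        rng = np.random.default_rng(5)
        pos = rng.random((N, 3)) * L0
        out = mc_fast.npt_lj_stage(
            pos, L0, beta, p_e, 40000, 10, 3.0, 0.0, 2.0, mc_fast.MODE_HARD,
            0.0, 3.0, 0.25, 0.25, False, 0.4, 100, 1.0, 42)
        vols = out[3]
        mean_v = vols[len(vols) // 4:].mean()
        sd = vols.std() / math.sqrt(len(vols) / 20)
        assert mean_v == pytest.approx(expected_V, rel=0.05)

    def test_same_seed_identical_trajectories(self):
        sp = StatePoint("methane-TraPPE", 64, 140.0, 1318.0, 7.0)
        plan = StagePlan.smoke()
        a = run_npt(sp, seed=3, plan=plan)
        b = run_npt(sp, seed=3, plan=plan)
        np.testing.assert_array_equal(a.rho, b.rho)
        np.testing.assert_array_equal(a.volume, b.volume)
        assert a.counters == b.counters


class TestGeneralEngine:
    def _methane_general(self, n=32, seed=4, n_mcc=60):
        sp = StatePoint("methane-TraPPE", n, 140.0, 1318.0, 6.0)
        snap = build_lattice_config(sp, seed=seed)
        ff = builtin_forcefields()["TraPPE-UA"].replace(r_cut=6.0,
                                                        lrc_mode="tail")
        eng = GeneralNptMC(snap, ff, sp, MoveSchedule(p_volume=0.02), seed=seed)
        return eng, n_mcc

    def test_energy_bookkeeping_drift(self):
        eng, n_mcc = self._methane_general()
        eng.run_stage(200, npt=True, adapt=True, sample_interval=50, T=140.0)
        full = eng.total_energy()
        assert abs(eng.u_total - full) <= 1e-6 * max(1.0, abs(full))

    def test_water_bookkeeping_with_ewald(self, water_toy, water_toy_sp):
        ff = builtin_forcefields()["SPC/E"].replace(r_cut=4.0)
        eng = GeneralNptMC(water_toy, ff, water_toy_sp,
                           MoveSchedule(p_volume=0.05, d_trans=0.25), seed=8)
        eng.run_stage(15, npt=True, adapt=True, sample_interval=5, T=300.0)
        full = eng.total_energy()
        assert abs(eng.u_total - full) <= 1e-6 * max(1.0, abs(full))

    def test_zero_displacement_always_accepted(self):
        eng, _ = self._methane_general()
        eng.schedule.d_trans = 0.0
        for _ in range(20):
            ok, du = eng.translate_move()
            assert ok and du == pytest.approx(0.0, abs=1e-12)

    def test_rotation_of_single_site_refused(self):
        eng, _ = self._methane_general()
        with pytest.raises(ValueError):
            eng.rotate_move(0)

    def test_incremental_du_matches_full_recompute(self):
        eng, _ = self._methane_general()
        for _ in range(25):
            before = eng.total_energy()
            ok, du = eng.translate_move()
            after = eng.total_energy()
            if ok:
                assert after - before == pytest.approx(du, abs=1e-9)

    def test_fast_and_general_engines_agree_statistically(self):
        """The numba path and the reference engine must sample the same
        density for the same LJ system."""
        sp = StatePoint("methane-TraPPE", 48, 140.0, 1318.0, 6.5)
        plan = StagePlan(melt_mcc=100, cool_mcc=100, equil_block_mcc=400,
                         max_equil_blocks=1, equil_check_mcc=200,
                         production_mcc=1500, sample_interval=5)
        fast = [run_npt(sp, seed=s, plan=plan, use_fast=True).rho_mean
                for s in (1, 2, 3)]
        gen = [run_npt(sp, seed=s, plan=plan, use_fast=False).rho_mean
               for s in (4, 5, 6)]
        spread = np.std(fast + gen, ddof=1)
        assert abs(np.mean(fast) - np.mean(gen)) < 4.0 * spread + 6.0


class TestAdaptation:
    def test_on_target_unchanged(self):
        s = MoveSchedule(d_trans=0.3)
        out = adapt_max_displacements({"translate": (100, 40)}, s, box=30.0)
        assert out.d_trans == pytest.approx(0.3)

    def test_high_acceptance_increases_displacement(self):
        s = MoveSchedule(d_trans=0.3)
        out = adapt_max_displacements({"translate": (100, 80)}, s, box=30.0)
        assert out.d_trans == pytest.approx(0.6)

    def test_clamped_to_quarter_box(self):
        s = MoveSchedule(d_trans=10.0)
        out = adapt_max_displacements({"translate": (100, 95)}, s, box=30.0)
        assert out.d_trans == 7.5

    def test_acceptance_converges_on_lj_fluid(self):
        sp = StatePoint("methane-TraPPE", 64, 140.0, 1318.0, 7.0)
        plan = StagePlan(melt_mcc=300, cool_mcc=300, equil_block_mcc=1200,
                         max_equil_blocks=1, equil_check_mcc=300,
                         production_mcc=1000)
        rec = run_npt(sp, seed=9, plan=plan)
        att, acc = rec.counters["translate"]
        # counters include early adaptation; production-dominated rate must
        # sit near the 40% target
        assert 0.25 <= acc / att <= 0.55


def butane_template():
    ref = _build_zmat([
        (0, 1.54, -1, 0, -1, 0),
        (1, 1.54, 0, 114.0, -1, 0),
        (2, 1.54, 1, 114.0, 0, 180.0),
    ])
    return MoleculeTemplate(
        name="butane", ff_name="TraPPE-UA",
        site_types=["CH3", "CH2", "CH2", "CH3"],
        bonds=[(0, 1, "CC"), (1, 2, "CC"), (2, 3, "CC")],
        angles=[(0, 1, 2, "CCC"), (1, 2, 3, "CCC")],
        dihedrals=[(0, 1, 2, 3, "CCCC")],
        rigidity="fixed_bonds", reference_coords=ref, rough_density=500.0)


class TestCBMC:
    def _gas_phase_engine(self, seed=21):
        tmpl = butane_template()
        templates = dict(builtin_models())
        templates["butane"] = tmpl
        ff = builtin_forcefields()["TraPPE-UA"].replace(r_cut=6.0,
                                                        lrc_mode="hard")
        coords = tmpl.reference_coords + 20.0
        snap = Snapshot(box=40.0, coords=coords, mol_index=np.zeros(4, int),
                        mol_templates=["butane"])
        sp = StatePoint("butane", 1, 372.0, 1402.0, 6.0)
        sched = MoveSchedule(n_first=4, n_bead=4, n_tors=50)
        return GeneralNptMC(snap, ff, sp, sched, seed=seed,
                            templates=templates), tmpl

    def test_fixed_bond_lengths_preserved(self):
        eng, tmpl = self._gas_phase_engine()
        for _ in range(60):
            eng.cbmc_regrow(0)
        p = eng.snap.coords
        for i, j, _ in tmpl.bonds:
            assert np.linalg.norm(p[j] - p[i]) == pytest.approx(1.54,
                                                                abs=1e-10)

    def test_gas_phase_dihedral_matches_boltzmann_quadrature(self):
        """Central oracle: with fixed bonds and no intramolecular nonbonded
        terms, the butane torsion marginal is exactly proportional to
        exp(-beta u(phi)) — compared against 1D quadrature of the cosine
        series."""
        eng, tmpl = self._gas_phase_engine()
        beta = 1.0 / (R_KJ * 372.0)
        term = eng.ff.dihedral_terms["CCCC"]
        phis = []
        for k in range(4000):
            eng.cbmc_regrow(0)
            phis.append(dihedral_angle(*eng.snap.coords[[0, 1, 2, 3]]))
        phis = np.array(phis[500:])
        edges = np.linspace(-math.pi, math.pi, 13)
        h, _ = np.histogram(phis, bins=edges)
        p_emp = h / h.sum()
        grid = np.linspace(-math.pi, math.pi, 20001)
        w = np.exp(-beta * term.energy(grid))
        p_exact = np.array([
            np.trapezoid(w[(grid >= a) & (grid <= b)],
                         grid[(grid >= a) & (grid <= b)])
            for a, b in zip(edges[:-1], edges[1:])])
        p_exact /= p_exact.sum()
        np.testing.assert_allclose(p_emp, p_exact, atol=0.05)

    def test_single_bead_regrowth_reduces_to_unbiased_sampling(self):
        """Whole-molecule regrowth of a free LJ bead with one trial is a plain
        Metropolis jump move; its equilibrium pair-distance distribution must
        match the translation-move chain."""
        ff, tmpl = lj_single_site(rc=6.0)
        templates = {"a": tmpl["a"]}
        sp = StatePoint("a", 2, 160.0, 1000.0, 6.0)
        L = 13.0

        def chain(kind, seed):
            snap = Snapshot(box=L, coords=np.array([[2, 2, 2], [6, 6, 6.0]]),
                            mol_index=np.arange(2), mol_templates=["a", "a"])
            eng = GeneralNptMC(snap, ff, sp,
                               MoveSchedule(n_first=1, d_trans=3.0),
                               seed=seed, templates=templates)
            dists = []
            for k in range(4000):
                if kind == "regrow":
                    eng.cbmc_regrow(int(k % 2))
                else:
                    eng.translate_move(int(k % 2))
                d = eng.snap.coords[1] - eng.snap.coords[0]
                d -= L * np.round(d / L)
                dists.append(np.linalg.norm(d))
            return np.array(dists[400:])

        edges = np.linspace(0, L / 2, 7)
        p_r = np.histogram(chain("regrow", 31), bins=edges)[0]
        p_t = np.histogram(chain("translate", 32), bins=edges)[0]
        p_r = p_r / p_r.sum()
        p_t = p_t / p_t.sum()
        np.testing.assert_allclose(p_r, p_t, atol=0.08)


def test_cutoff_scan_deterministic_and_ordered():
    sp = StatePoint("methane-TraPPE", 48, 140.0, 1318.0, 6.0)
    plan = StagePlan.smoke()
    df1 = run_cutoff_scan(sp, [5.0, 6.0], "tail", seeds=[1, 2], plan=plan)
    df2 = run_cutoff_scan(sp, [6.0, 5.0], "tail", seeds=[1, 2], plan=plan)
    assert np.allclose(df1.rho_mean.values, df2.rho_mean.values)
    assert df1.asymptotic_error_pct.iloc[-1] == 0.0
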