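"""Single-point energies: pair potential, tails, Ewald, bonded terms."""

import math

import numpy as np
import pytest
from scipy import integrate

from replibench.configio import Snapshot, build_lattice_config, random_rotation_matrix
from replibench.constants import COULOMB_KJ_A, KJMOL_A3_TO_KPA, R_KJ
from replibench.energy import (
    EwaldSettings,
    compare_single_points,
    dihedral_angle,
    ewald_energy,
    lj_pair_energy,
    single_point,
    tail_corrections,
)
from replibench.ffparams import AtomType, ForceField, LJParameters
from replibench.models import MoleculeTemplate, StatePoint, builtin_forcefields


# ---------------------------------------------------------------------------
# helpers: single-site ion/LJ scaffolding
# ---------------------------------------------------------------------------

def ion_system():
    ff = ForceField(
        name="ions",
        atom_types={
            "NA": AtomType(LJParameters(1.0, 0.0), 1.0, 22.99),
            "CL": AtomType(LJParameters(1.0, 0.0), -1.0, 35.45),
        },
        r_cut=3.9, lrc_mode="hard",
    )
    tmpl = {
        "na": MoleculeTemplate("na", "ions", ["NA"], rigidity="point",
                               reference_coords=np.zeros((1, 3))),
        "cl": MoleculeTemplate("cl", "ions", ["CL"], rigidity="point",
                               reference_coords=np.zeros((1, 3))),
    }
    return ff, tmpl


class TestLJPair:
    def test_zero_at_sigma(self):
        assert lj_pair_energy(3.73, 3.73, 1.0, 14.0) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth(self):
        r = 2 ** (1 / 6) * 3.73
        assert lj_pair_energy(r, 3.73, 1.23, 14.0) == pytest.approx(-1.23, rel=1e-12)

    def test_shifted_vanishes_at_cutoff(self):
        u = lj_pair_energy(13.999999, 3.73, 1.23, 14.0, mode="shifted")
        assert abs(u) < 1e-9

    def test_zero_beyond_cutoff(self):
        assert lj_pair_energy(14.5, 3.73, 1.23, 14.0) == 0.0

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            lj_pair_energy(0.0, 3.73, 1.23, 14.0)


class TestTailCorrections:
    def _one_component(self, N=64, L=40.0, sigma=3.73, eps=1.2, rc=10.0):
        ff = ForceField(
            name="lj", atom_types={"A": AtomType(LJParameters(sigma, eps), 0.0, 16.0)},
            r_cut=rc, lrc_mode="tail")
        tmpl = {"a": MoleculeTemplate("a", "lj", ["A"], rigidity="point",
                                      reference_coords=np.zeros((1, 3)))}
        snap = Snapshot(box=L, coords=np.random.default_rng(0).random((N, 3)) * L,
                        mol_index=np.arange(N), mol_templates=["a"] * N)
        return snap, ff, tmpl, N, L, sigma, eps, rc

    def test_energy_matches_quadrature(self):
        snap, ff, tmpl, N, L, sigma, eps, rc = self._one_component()
        u_tail, p_tail = tail_corrections(snap, ff, tmpl)
        # U_tail = (N^2/2) * (1/V) * int_rc^inf 4 pi r^2 u(r) dr
        integrand = lambda r: 4 * math.pi * r * r * 4 * eps * (
            (sigma / r) ** 12 - (sigma / r) ** 6)
        val, err = integrate.quad(integrand, rc, np.inf)
        expected = 0.5 * N * N / L**3 * val
        assert u_tail == pytest.approx(expected, rel=1e-8)

    def test_pressure_matches_quadrature(self):
        snap, ff, tmpl, N, L, sigma, eps, rc = self._one_component()
        _, p_tail = tail_corrections(snap, ff, tmpl)
        # p_tail = -(2 pi /3) rho^2 int r^3 du/dr dr (standard virial tail)
        dudr = lambda r: 4 * eps * (-12 * sigma**12 / r**13 + 6 * sigma**6 / r**7)
        val, _ = integrate.quad(lambda r: r**3 * dudr(r), rc, np.inf)
        expected = -(2 * math.pi / 3) * (N / L**3) ** 2 * val * KJMOL_A3_TO_KPA
        assert p_tail == pytest.approx(expected, rel=1e-8)

    def test_vanishes_at_large_cutoff(self):
        snap, ff, tmpl, *_ = self._one_component(rc=18.0, L=40.0)
        u18, p18 = tail_corrections(snap, ff.replace(r_cut=18.0), tmpl)
        snap2, ff2, tmpl2, *_ = self._one_component(rc=10.0)
        u10, p10 = tail_corrections(snap2, ff2, tmpl2)
        assert abs(u18) < abs(u10)
        assert abs(u18) < 0.05 * abs(u10) * 18 ** 3 / 10 ** 3  # ~ rc^-3 decay

    def test_doubling_volume_halves_energy_tail(self):
        snap, ff, tmpl, *_ = self._one_component()
        u1, _ = tail_corrections(snap, ff, tmpl)
        big = snap.copy()
        big.box = snap.box * 2 ** (1 / 3)
        u2, _ = tail_corrections(big, ff, tmpl)
        assert u2 == pytest.approx(u1 / 2, rel=1e-12)

    def test_zero_unless_tail_mode(self):
        snap, ff, tmpl, *_ = self._one_component()
        assert tail_corrections(snap, ff.replace(lrc_mode="hard"), tmpl) == (0.0, 0.0)


class TestEwald:
    def test_all_charges_zero(self, methane_toy, forcefields):
        ff = forcefields["TraPPE-UA"].replace(r_cut=7.0)
        comp = ewald_energy(methane_toy, ff)
        assert comp == {"real": 0.0, "reciprocal": 0.0, "self": 0.0,
                        "exclusion": 0.0}

    def test_rock_salt_madelung(self):
        ff, tmpl = ion_system()
        a, ncell = 2.0, 4
        L = a * ncell
        pos, q = [], []
        for i in range(2 * ncell):
            for j in range(2 * ncell):
                for k in range(2 * ncell):
                    pos.append([i * a / 2, j * a / 2, k * a / 2])
                    q.append(1 if (i + j + k) % 2 == 0 else -1)
        pos = np.array(pos, dtype=float)
        names = ["na" if qq > 0 else "cl" for qq in q]
        snap = Snapshot(box=L, coords=pos, mol_index=np.arange(len(q)),
                        mol_templates=names)
        st = EwaldSettings(kappa=3.6 / 3.9, kmax=int(3.6 / 3.9 * L) + 1,
                           accuracy=1e-10)
        comp = ewald_energy(snap, ff, st, templates=tmpl)
        u = sum(comp.values())
        n_pairs = len(q) // 2
        madelung = -u / n_pairs / COULOMB_KJ_A * (a / 2)
        # real space truncated at erfc(kappa r_cut) ~ 4e-7 -> ppm-level check
        assert madelung == pytest.approx(1.747564594633, rel=2e-6)

    def test_isolated_dipole_limit(self):
        ff, tmpl = ion_system()
        d = 2.0
        vals = []
        for L in (60.0, 120.0):
            snap = Snapshot(box=L, coords=np.array([[0, 0, 0], [d, 0, 0.0]]),
                            mol_index=np.arange(2), mol_templates=["na", "cl"])
            st = EwaldSettings(kappa=3.6 / 25.0, kmax=int(3.6 / 25.0 * L) + 1,
                               accuracy=1e-9)
            comp = ewald_energy(snap, ff.replace(r_cut=L / 2 - 1), st,
                                templates=tmpl)
            vals.append(sum(comp.values()))
        exact = -COULOMB_KJ_A / d
        assert abs(vals[1] - exact) < abs(vals[0] - exact)
        assert vals[1] == pytest.approx(exact, rel=1e-4)

    def test_total_stable_under_kappa_variation(self, water_toy, forcefields):
        # kappa r_cut >= 4.8 keeps the erfc real-space truncation below the
        # 1e-10 reciprocal target, so the split itself must not matter
        ff = forcefields["SPC/E"].replace(r_cut=4.0)
        totals = []
        for f in (0.8, 1.0, 1.2):
            kappa = f * 6.0 / 4.0
            st = EwaldSettings(kappa=kappa, kmax=int(kappa * water_toy.box) + 1,
                               accuracy=1e-11)
            comp = ewald_energy(water_toy, ff, st)
            totals.append(sum(comp.values()))
        assert max(totals) - min(totals) <= 1e-8 * abs(totals[1])

    def test_non_neutral_refused(self):
        ff, tmpl = ion_system()
        snap = Snapshot(box=20.0, coords=np.array([[0, 0, 0.0], [3, 0, 0]]),
                        mol_index=np.arange(2), mol_templates=["na", "na"])
        with pytest.raises(ValueError, match="non-neutral"):
            ewald_energy(snap, ff, templates=tmpl)


class TestBonded:
    def test_equilibrium_geometry_zero_bond_angle_energy(self, models,
                                                         forcefields):
        sp = StatePoint("ethanol-OPLS", 2, 300.0, 101.325, 4.0)
        snap = build_lattice_config(sp, seed=1, density_guess=80.0)
        ff = forcefields["OPLS-AA-ethanol"].replace(r_cut=4.0)
        rep = single_point(snap, ff)
        assert rep.bond == pytest.approx(0.0, abs=1e-18)
        # tetrahedral equilibrium angles are mutually incompatible, so the
        # reference geometry leaves a small residual (< 0.1 kJ/mol for two
        # molecules) rather than exactly zero
        assert 0.0 <= rep.angle < 0.1

    def test_displaced_angle_harmonic_closed_form(self, models, forcefields):
        tmpl = models["water-SPC/E"]
        ff = forcefields["SPC/E"]
        # flexible variant of the HOH angle for this check
        ff2 = ff.replace(r_cut=4.0)
        ff2.angle_terms["HOH"].k = 300.0
        dtheta = 0.05
        half = math.radians((109.47 + math.degrees(2 * dtheta)) / 2)
        coords = np.array([
            [0, 0, 0],
            [math.cos(half), math.sin(half), 0],
            [math.cos(half), -math.sin(half), 0.0],
        ])
        snap = Snapshot(box=20.0, coords=coords + 10.0, mol_index=np.zeros(3, int),
                        mol_templates=["water-SPC/E"])
        rep = single_point(snap, ff2)
        assert rep.angle == pytest.approx(0.5 * 300.0 * (2 * dtheta) ** 2,
                                          rel=1e-9)

    def test_pentane_trans_gauche_difference_matches_series(self, models,
                                                            forcefields):
        tmpl = models["pentane-TraPPE"]
        ff = forcefields["TraPPE-UA"].replace(r_cut=6.0)
        term = ff.dihedral_terms["CCCC"]
        snap_t = build_lattice_config(
            StatePoint("pentane-TraPPE", 1, 372.0, 1402.0, 6.0), seed=1,
            density_guess=20.0)
        rep_t = single_point(snap_t, ff)
        phi = [dihedral_angle(*snap_t.coords[[i, j, k, l]])
               for i, j, k, l, _ in tmpl.dihedrals]
        expected = sum(float(term.energy(p)) for p in phi)
        assert rep_t.dihedral == pytest.approx(expected, rel=1e-12)
        # all-trans reference geometry sits at the series minimum (phi = pi)
        assert rep_t.dihedral == pytest.approx(2 * float(term.energy(math.pi)),
                                               abs=1e-9)


class TestSinglePoint:
    def test_two_sites_at_minimum(self):
        ff = ForceField(
            name="lj", atom_types={"A": AtomType(LJParameters(3.73, 1.23), 0.0,
                                                 16.0)},
            r_cut=12.0, lrc_mode="hard")
        tmpl = {"a": MoleculeTemplate("a", "lj", ["A"], rigidity="point",
                                      reference_coords=np.zeros((1, 3)))}
        r = 2 ** (1 / 6) * 3.73
        snap = Snapshot(box=30.0, coords=np.array([[5, 5, 5], [5 + r, 5, 5.0]]),
                        mol_index=np.arange(2), mol_templates=["a", "a"])
        rep = single_point(snap, ff, templates=tmpl)
        assert rep.total == pytest.approx(-1.23, rel=1e-12)

    def test_bit_identical_reports(self, water_toy, forcefields):
        ff = forcefields["SPC/E"].replace(r_cut=4.0)
        a = single_point(water_toy, ff)
        b = single_point(water_toy, ff)
        assert a.total == b.total
        assert a.components == b.components

    def test_decomposition_identity(self, water_toy, forcefields):
        ff = forcefields["SPC/E"].replace(r_cut=4.0)
        rep = single_point(water_toy, ff)
        assert rep.total == pytest.approx(sum(rep.components.values()),
                                          rel=1e-10)

    def test_tail_and_shift_fields_track_mode(self, methane_toy, forcefields):
        base = forcefields["TraPPE-UA"].replace(r_cut=7.0)
        rep_tail = single_point(methane_toy, base.replace(lrc_mode="tail"))
        rep_hard = single_point(methane_toy, base.replace(lrc_mode="hard"))
        rep_shift = single_point(methane_toy, base.replace(lrc_mode="shifted"))
        assert rep_tail.lj_tail != 0.0
        assert rep_hard.lj_tail == 0.0 and rep_shift.lj_tail == 0.0
        assert rep_shift.lj_shift_applied and not rep_hard.lj_shift_applied
        # shifting up by -u(r_cut) (> 0) raises the pair sum
        assert rep_shift.lj_pair > rep_hard.lj_pair

    @pytest.mark.parametrize("model,n,rc,rot_tol", [
        ("methane-TraPPE", 27, 6.0, 1e-9),
        ("pentane-TraPPE", 8, 6.0, 1e-9),
        ("benzene-TraPPE", 8, 6.0, 1e-9),
        # charged models: periodic-image electrostatics are genuinely not
        # rotation invariant; only the image-interaction residual remains
        ("water-SPC/E", 16, 4.0, 2e-3),
        ("ethanol-OPLS", 8, 5.0, 2e-3),
    ])
    def test_translation_rotation_invariance(self, models, forcefields,
                                             model, n, rc, rot_tol, rng):
        # cluster in a 3x larger box: every pair distance stays far from the
        # minimum-image boundary, where periodic systems are not rotation
        # invariant by construction
        sp = StatePoint(model, n, 300.0, 101.325, rc)
        snap = build_lattice_config(sp, seed=9)
        snap.box *= 3.0
        ff = forcefields[models[model].ff_name].replace(r_cut=rc,
                                                        lrc_mode="hard")
        ref = single_point(snap, ff)
        # global translation (exact for minimum image and Ewald phases)
        t = snap.copy()
        t.coords = t.coords + np.array([1.7, -0.4, 2.9])
        assert single_point(t, ff).total == pytest.approx(ref.total, rel=1e-9)
        # global rigid rotation about the cluster centroid
        R = random_rotation_matrix(rng)
        c = snap.coords.mean(axis=0)
        r = snap.copy()
        r.coords = (r.coords - c) @ R.T + c
        rot = single_point(r, ff)
        assert rot.total == pytest.approx(ref.total, rel=rot_tol)
        # the short-ranged part is exactly invariant for every model
        short = lambda rep: (rep.lj_pair + rep.bond + rep.angle
                             + rep.dihedral + rep.intra_nonbonded)
        assert short(rot) == pytest.approx(short(ref), rel=1e-9)

    def test_ideal_gas_virial_pressure(self):
        from replibench.energy import virial_pressure_kpa
        ff = ForceField(
            name="ideal", atom_types={"A": AtomType(LJParameters(3.0, 0.0),
                                                    0.0, 16.0)},
            r_cut=6.0, lrc_mode="hard")
        tmpl = {"a": MoleculeTemplate("a", "ideal", ["A"], rigidity="point",
                                      reference_coords=np.zeros((1, 3)))}
        N, L, T = 50, 30.0, 300.0
        snap = Snapshot(box=L, coords=np.random.default_rng(1).random((N, 3)) * L,
                        mol_index=np.arange(N), mol_templates=["a"] * N)
        rep = single_point(snap, ff, templates=tmpl)
        p = virial_pressure_kpa(rep, N, T, L**3)
        expected = N * R_KJ * T / L**3 * KJMOL_A3_TO_KPA
        assert p == pytest.approx(expected, rel=1e-12)

    def test_small_box_refused(self, methane_toy, forcefields):
        ff = forcefields["TraPPE-UA"].replace(r_cut=0.6 * methane_toy.box)
        with pytest.raises(ValueError, match="2\\*r_cut"):
            single_point(methane_toy, ff)

    def test_overlap_sentinel(self):
        ff = ForceField(
            name="lj", atom_types={"A": AtomType(LJParameters(3.73, 1.23),
                                                 0.0, 16.0)},
            r_cut=6.0, lrc_mode="hard")
        tmpl = {"a": MoleculeTemplate("a", "lj", ["A"], rigidity="point",
                                      reference_coords=np.zeros((1, 3)))}
        snap = Snapshot(box=20.0, coords=np.array([[5, 5, 5], [5.5, 5, 5.0]]),
                        mol_index=np.arange(2), mol_templates=["a", "a"])
        rep = single_point(snap, ff, templates=tmpl)
        assert math.isinf(rep.total)


class TestCompareSinglePoints:
    def test_identical_reports_all_zero(self, methane_toy, forcefields):
        ff = forcefields["TraPPE-UA"].replace(r_cut=7.0)
        rep = single_point(methane_toy, ff)
        df = compare_single_points([rep, rep, rep])
        assert np.allclose(df.rel_error_x1e5, 0.0)

    def test_pdb_truncation_error_magnitude(self, methane_toy, forcefields):
        from replibench.configio import truncate_coordinates
        ff = forcefields["TraPPE-UA"].replace(r_cut=7.0)
        a = single_point(methane_toy, ff)
        b = single_point(truncate_coordinates(methane_toy, "pdb"), ff)
        df = compare_single_points([a, b], labels=["lossless", "pdb"])
        err = abs(df[df.label == "pdb"].rel_error_x1e5.iloc[0]) / 1e5
        assert 1e-7 < err < 1e-2

    def test_errors_mean_zero(self, methane_toy, forcefields):
        from replibench.configio import truncate_coordinates
        ff = forcefields["TraPPE-UA"].replace(r_cut=7.0)
        reps = [single_point(truncate_coordinates(methane_toy, d), ff)
                for d in ("lossless", "f32", "pdb")]
        df = compare_single_points(reps)
        assert df.rel_error_x1e5.mean() == pytest.approx(0.0, abs=1e-6)
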