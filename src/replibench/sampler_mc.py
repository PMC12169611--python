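"""NpT Metropolis Monte Carlo: move schedule, staged workflow, CBMC regrowth.

Workflow (per replicate): a seeded lattice configuration is melted in the NVT
ensemble at 1000 K, cooled at the target temperature, equilibrated in NpT
(maximum displacements adapted toward a 40% acceptance target, equilibration
gated by the statistical-inefficiency test), then sampled in a production NpT
stage with frozen move parameters.  One MC cycle (MCC) is N attempted moves.
Volume moves are proposed uniformly in ln V and accepted with
min[1, exp(-beta dU - beta p dV + (N+1) ln(V'/V))]; number and specific
densities are accumulated after every attempted move so every configuration
carries the same weight.

Two engines share these conventions: a general pure-numpy engine supporting
all five models (Ewald electrostatics, rigid-body rotations, CBMC regrowth)
and a numba fast path for single-site LJ fluids (``mc_fast``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import erf, erfc

from . import mc_fast
from .configio import Snapshot, build_lattice_config, random_rotation_matrix
from .constants import COULOMB_KJ_A, DENSITY_FACTOR, KPA_A3_TO_KJMOL, R_KJ
from .energy import (
    EwaldSettings,
    PairTable,
    R_MIN,
    _kvectors,
    bonded_energy,
    single_point,
    tail_corrections,
)
from .ffparams import ForceField
from .models import (
    MoleculeTemplate,
    StatePoint,
    builtin_forcefields,
    builtin_models,
)

__all__ = [
    "MoveSchedule",
    "StagePlan",
    "TrajectoryRecord",
    "CBMC_PRESETS",
    "GeneralNptMC",
    "run_npt",
    "run_cutoff_scan",
    "adapt_max_displacements",
    "metropolis_probability",
]

#: (first-bead trials, subsequent-bead trials, torsion trials) presets
CBMC_PRESETS = {
    "mcccs": (16, 8, 100),
    "gomc": (12, 10, 50),
    "cassandra": (16, 8, 50),
}


def metropolis_probability(delta_u: float, beta: float, extra_log: float = 0.0) -> float:
    """Acceptance probability min(1, exp(-beta dU + extra_log))."""
    arg = -beta * delta_u + extra_log
    if arg >= 0.0:
        return 1.0
    return math.exp(arg)


@dataclass
class MoveSchedule:
    """Move probabilities, maximum displacements, and CBMC trial counts.

    ``p_volume`` defaults to 0.01, or 2.5/N for charged systems (one accepted
    volume move per MCC); the remainder is split equally over translation,
    rigid rotation (all molecules except single sites) and regrowth (flexible
    or fixed-bond polyatomics only).
    """

    p_volume: float = 0.01
    d_trans: float = 0.3        # Å
    d_rot: float = 0.35         # rad
    d_lnv: float = 0.02
    target_acceptance: float = 0.4
    n_first: int = 16
    n_bead: int = 8
    n_tors: int = 100
    adapt_interval: int = 100   # MCC between adaptation updates
    rotation_style: str = "random_axis"   # or "cartesian"

    @classmethod
    def default_for(cls, sp: StatePoint, tmpl: MoleculeTemplate,
                    ff: ForceField, preset: str = "mcccs") -> "MoveSchedule":
        charged = any(ff.atom_types[t].charge != 0.0 for t in tmpl.site_types)
        n1, nb, nt = CBMC_PRESETS[preset]
        return cls(p_volume=(2.5 / sp.N if charged else 0.01),
                   n_first=n1, n_bead=nb, n_tors=nt)

    def move_kinds(self, tmpl: MoleculeTemplate) -> list[str]:
        kinds = ["translate"]
        if tmpl.n_sites > 1:
            kinds.append("rotate")
        if tmpl.rigidity in ("fixed_bonds", "flexible") and tmpl.n_sites > 1:
            kinds.append("regrow")
        return kinds


@dataclass
class StagePlan:
    """Stage lengths in MC cycles (one MCC = N attempted moves)."""

    melt_mcc: int = 5000
    cool_mcc: int = 5000
    equil_block_mcc: int = 40000
    max_equil_blocks: int = 3
    equil_check_mcc: int = 10000
    production_mcc: int = 120000
    melt_T: float = 1000.0
    sample_interval: int = 10   # MCC between samples

    @classmethod
    def desk(cls) -> "StagePlan":
        """Desk-scale preset for reduced-N replicate campaigns."""
        return cls(melt_mcc=500, cool_mcc=500, equil_block_mcc=4000,
                   max_equil_blocks=3, equil_check_mcc=2000,
                   production_mcc=16000)

    @classmethod
    def smoke(cls) -> "StagePlan":
        """Minimal preset for functional tests."""
        return cls(melt_mcc=50, cool_mcc=50, equil_block_mcc=100,
                   max_equil_blocks=1, equil_check_mcc=50, production_mcc=200,
                   sample_interval=5)


@dataclass
class TrajectoryRecord:
    """Density/volume/energy time series with stage labels and accumulators."""

    model: str
    sp: StatePoint
    seed: int
    mcc: np.ndarray
    volume: np.ndarray
    rho: np.ndarray
    u_total: np.ndarray
    stage_labels: list[str]
    counters: dict
    prod_acc_rho: float      # sum of specific density over attempted moves
    prod_acc_n: float
    final_box: float
    final_schedule: "MoveSchedule"
    method: str = "mc"
    label: str = ""

    @property
    def rho_mean(self) -> float:
        """Production mean specific density from the every-move accumulator."""
        return self.prod_acc_rho / self.prod_acc_n

    def stage(self, name: str) -> np.ndarray:
        mask = np.array([s == name for s in self.stage_labels])
        return mask

    def rho_production(self) -> np.ndarray:
        return self.rho[self.stage("production")]


def adapt_max_displacements(counters: dict, schedule: MoveSchedule,
                            box: float) -> MoveSchedule:
    """Multiplicative update of maximum displacements toward the target
    acceptance, clamped (d_trans <= L/4, d_rot <= pi, d_lnv <= 0.5).

    ``counters`` maps move kind to (attempted, accepted) since the last update.
    """
    new = dc_replace(schedule)
    for kind, (att, acc) in counters.items():
        if att == 0:
            continue
        f = min(2.0, max(0.5, (acc / att) / schedule.target_acceptance))
        if kind == "translate":
            new.d_trans = min(box / 4.0, max(1e-3, schedule.d_trans * f))
        elif kind == "rotate":
            new.d_rot = min(math.pi, max(1e-3, schedule.d_rot * f))
        elif kind == "volume":
            new.d_lnv = min(0.5, max(1e-5, schedule.d_lnv * f))
    return new


# ---------------------------------------------------------------------------
# general engine
# ---------------------------------------------------------------------------

class GeneralNptMC:
    """Reference NpT MC engine for arbitrary molecular models.

    Incremental energies: molecule-vs-rest LJ and erfc-screened real-space
    Coulomb, reciprocal-space Ewald via structure-factor updates, bonded and
    intramolecular terms recomputed for the moved molecule only.  The running
    total is cross-checked against a full re-evaluation in the test suite.
    """

    def __init__(self, snap: Snapshot, ff: ForceField, sp: StatePoint,
                 schedule: MoveSchedule, seed: int,
                 templates: dict[str, MoleculeTemplate] | None = None,
                 flexible_bonds: bool = False):
        self.templates = templates or builtin_models()
        self.snap = snap.copy()
        self.ff = ff
        self.sp = sp
        self.schedule = schedule
        self.rng = np.random.default_rng(seed)
        self.flexible_bonds = flexible_bonds
        self.table = PairTable(self.snap, ff, self.templates)
        self.slices = self.snap.mol_slices()
        self.tmpls = [self.templates[t] for t in self.snap.mol_templates]
        self.beta = 1.0 / (R_KJ * sp.T)
        self.kinds = self.schedule.move_kinds(self.tmpls[0])
        self._dih_offsets = {
            key: float(np.min(term.energy(np.linspace(0, 2 * math.pi, 720))))
            for key, term in ff.dihedral_terms.items()
        }
        self._setup_ewald()
        self.u_total = self.total_energy()
        self.T = sp.T

    # -- energy machinery ---------------------------------------------------

    def _setup_ewald(self):
        if not self.table.has_charges:
            self.kvec = None
            return
        self.ewald = EwaldSettings.from_system(self.ff.r_cut, self.snap.box)
        self.kvec = _kvectors(self.ewald.kmax, self.snap.box)
        self._rebuild_recip()

    def _rebuild_recip(self):
        L = self.snap.box
        k = 2.0 * math.pi * self.kvec / L
        self._k = k
        k2 = (k**2).sum(axis=1)
        self._A = np.exp(-k2 / (4.0 * self.ewald.kappa**2)) / k2
        self._recip_C = COULOMB_KJ_A * (2.0 * math.pi / L**3) * 2.0
        phase = self.snap.coords @ k.T
        self._S = (self.table.charges[:, None] * np.exp(1j * phase)).sum(axis=0)

    def _u_recip(self, S=None) -> float:
        if self.kvec is None:
            return 0.0
        S = self._S if S is None else S
        return self._recip_C * float(np.sum(self._A * np.abs(S) ** 2))

    def _mol_nb(self, m: int, coords_mol: np.ndarray) -> float:
        """LJ + real-space Coulomb of molecule m (at given coordinates) with
        all other molecules; +inf on hard-core overlap."""
        sl = self.slices[m]
        others = np.ones(self.snap.n_sites, dtype=bool)
        others[sl] = False
        pos_o = self.snap.coords[others]
        L = self.snap.box
        d = pos_o[None, :, :] - coords_mol[:, None, :]
        d -= L * np.round(d / L)
        r2 = (d**2).sum(axis=-1)
        if np.any(r2 < R_MIN * R_MIN):
            return math.inf
        rc2 = self.ff.r_cut**2
        mask = r2 <= rc2
        t_m = self.table.site_type[sl]
        t_o = self.table.site_type[others]
        sig = self.table.sigma[t_m][:, t_o]
        eps = self.table.eps[t_m][:, t_o]
        u = 0.0
        if mask.any():
            s6 = (sig[mask] ** 2 / r2[mask]) ** 3
            e = eps[mask]
            uu = 4.0 * e * (s6 * s6 - s6)
            if self.ff.lrc_mode == "shifted":
                xc6 = (sig[mask] / self.ff.r_cut) ** 6
                uu -= 4.0 * e * (xc6 * xc6 - xc6)
            u += float(uu.sum())
            if self.table.has_charges:
                q_m = self.table.charges[sl]
                q_o = self.table.charges[others]
                qq = np.outer(q_m, q_o)[mask]
                r = np.sqrt(r2[mask])
                u += COULOMB_KJ_A * float(
                    np.sum(qq * erfc(self.ewald.kappa * r) / r))
        return u

    def _mol_intra(self, m: int, coords_mol: np.ndarray) -> float:
        """Bonded + scaled intramolecular nonbonded + Ewald exclusion
        correction of molecule m at the given internal geometry."""
        tmpl = self.tmpls[m]
        if tmpl.n_sites == 1:
            return 0.0
        ff = self.ff
        u = 0.0
        p = coords_mol
        for i, j, key in tmpl.bonds:
            term = ff.bond_terms[key]
            if term.fixed or not self.flexible_bonds:
                continue
            r = float(np.linalg.norm(p[j] - p[i]))
            u += 0.5 * term.k * (r - term.r0) ** 2
        for i, j, k, key in tmpl.angles:
            term = ff.angle_terms[key]
            if term.k is None:
                continue
            u += 0.5 * term.k * (_angle(p[i], p[j], p[k]) - term.theta0_rad) ** 2
        for i, j, k, l, key in tmpl.dihedrals:
            from .energy import dihedral_angle
            u += float(ff.dihedral_terms[key].energy(
                dihedral_angle(p[i], p[j], p[k], p[l])))
        sl = self.slices[m]
        qm = self.table.charges[sl]
        tm = self.table.site_type[sl]
        kappa = self.ewald.kappa if self.kvec is not None else 0.0
        for i, j, slj, scoul in self.table.intra_pairs(tmpl.name):
            r = float(np.linalg.norm(p[j] - p[i]))
            if slj != 0.0:
                s = self.table.sigma[tm[i], tm[j]]
                e = self.table.eps[tm[i], tm[j]]
                x6 = (s / r) ** 6
                u += slj * 4.0 * e * (x6 * x6 - x6)
            if qm[i] != 0.0 and qm[j] != 0.0:
                if scoul != 0.0:
                    u += scoul * COULOMB_KJ_A * qm[i] * qm[j] / r
                if self.kvec is not None:
                    u -= COULOMB_KJ_A * qm[i] * qm[j] * float(erf(kappa * r)) / r
        return u

    def total_energy(self) -> float:
        """Full re-evaluation of the tracked potential energy (pair + recip +
        self + intra + tail).  Used at stage boundaries and as the bookkeeping
        oracle."""
        u = 0.0
        for m in range(self.snap.n_molecules):
            u += 0.5 * self._mol_nb(m, self.snap.coords[self.slices[m]])
            u += self._mol_intra(m, self.snap.coords[self.slices[m]])
        if self.kvec is not None:
            u += self._u_recip()
            u += -COULOMB_KJ_A * self.ewald.kappa / math.sqrt(math.pi) * float(
                np.sum(self.table.charges**2))
        u_tail, _ = tail_corrections(self.snap, self.ff, self.templates,
                                     table=self.table)
        return u + u_tail

    def _delta_S(self, m: int, new_coords: np.ndarray):
        if self.kvec is None:
            return None
        sl = self.slices[m]
        q = self.table.charges[sl]
        old = self.snap.coords[sl]
        dS = (q[:, None] * (np.exp(1j * (new_coords @ self._k.T))
                            - np.exp(1j * (old @ self._k.T)))).sum(axis=0)
        return dS

    # -- moves --------------------------------------------------------------

    def translate_move(self, m: int | None = None) -> tuple[bool, float]:
        if m is None:
            m = int(self.rng.integers(self.snap.n_molecules))
        sl = self.slices[m]
        old = self.snap.coords[sl].copy()
        disp = (self.rng.random(3) * 2.0 - 1.0) * self.schedule.d_trans
        new = old + disp
        return self._accept_rigid(m, sl, old, new)

    def rotate_move(self, m: int | None = None) -> tuple[bool, float]:
        if m is None:
            m = int(self.rng.integers(self.snap.n_molecules))
        if self.tmpls[m].n_sites == 1:
            raise ValueError("rotation of a single-site molecule")
        sl = self.slices[m]
        old = self.snap.coords[sl].copy()
        com = old.mean(axis=0)
        angle = (self.rng.random() * 2.0 - 1.0) * self.schedule.d_rot
        if self.schedule.rotation_style == "cartesian":
            axis = np.zeros(3)
            axis[self.rng.integers(3)] = 1.0
        else:
            v = self.rng.normal(size=3)
            axis = v / np.linalg.norm(v)
        R = _axis_angle(axis, angle)
        new = (old - com) @ R.T + com
        return self._accept_rigid(m, sl, old, new)

    def _accept_rigid(self, m, sl, old, new) -> tuple[bool, float]:
        u_old = self._mol_nb(m, old)
        u_new = self._mol_nb(m, new)
        if math.isinf(u_new):
            return False, 0.0
        dS = self._delta_S(m, new)
        du_recip = 0.0
        if dS is not None:
            du_recip = self._u_recip(self._S + dS) - self._u_recip()
        du = u_new - u_old + du_recip
        if self.rng.random() < metropolis_probability(du, self.beta):
            self.snap.coords[sl] = new
            if dS is not None:
                self._S += dS
            self.u_total += du
            return True, du
        return False, 0.0

    def volume_move(self) -> tuple[bool, float]:
        L = self.snap.box
        V = L**3
        dln = (self.rng.random() * 2.0 - 1.0) * self.schedule.d_lnv
        Vn = V * math.exp(dln)
        Ln = Vn ** (1.0 / 3.0)
        if Ln < 2.0 * self.ff.r_cut:
            return False, 0.0
        s = Ln / L
        old_coords = self.snap.coords.copy()
        new_coords = old_coords.copy()
        for sl in self.slices:
            com = old_coords[sl].mean(axis=0)
            new_coords[sl] = old_coords[sl] + com * (s - 1.0)
        u_old = self.u_total
        old_box = self.snap.box
        old_S = self._S.copy() if self.kvec is not None else None
        self.snap.coords = new_coords
        self.snap.box = Ln
        if self.kvec is not None:
            self.ewald = EwaldSettings.from_system(self.ff.r_cut, Ln)
            self.kvec = _kvectors(self.ewald.kmax, Ln)
            self._rebuild_recip()
        u_new = self.total_energy()
        n = self.snap.n_molecules
        du = u_new - u_old
        extra = (n + 1) * dln - self.beta * self.sp.p * KPA_A3_TO_KJMOL * (Vn - V)
        if not math.isinf(u_new) and self.rng.random() < metropolis_probability(
                du, self.beta, extra):
            self.u_total = u_new
            return True, du
        self.snap.coords = old_coords
        self.snap.box = old_box
        if self.kvec is not None:
            self.ewald = EwaldSettings.from_system(self.ff.r_cut, old_box)
            self.kvec = _kvectors(self.ewald.kmax, old_box)
            self._rebuild_recip()
            if old_S is not None:
                self._S = old_S
        return False, 0.0

    # -- CBMC regrowth ------------------------------------------------------

    def _regrow_order(self, tmpl: MoleculeTemplate):
        """Choose a cut uniformly over (bond, side) pairs plus whole-molecule
        regrowth; return (kept set, BFS order of regrown beads)."""
        nbr = {i: [] for i in range(tmpl.n_sites)}
        for i, j, _ in tmpl.bonds:
            nbr[i].append(j)
            nbr[j].append(i)
        options: list[tuple] = [("whole", None)]
        for i, j, _ in tmpl.bonds:
            options.append(("cut", (i, j)))
            options.append(("cut", (j, i)))
        kind, cut = options[int(self.rng.integers(len(options)))]
        if kind == "whole":
            root = int(self.rng.integers(tmpl.n_sites))
            kept = set()
            order = [root]
        else:
            keep_side, grow_root = cut
            kept = set()
            stack = [keep_side]
            seen = {keep_side, grow_root}
            while stack:
                a = stack.pop()
                kept.add(a)
                for b in nbr[a]:
                    if b not in seen:
                        seen.add(b)
                        stack.append(b)
            order = [grow_root]
        placed = set(kept) | {order[0]}
        queue = [order[0]]
        while queue:
            a = queue.pop(0)
            for b in nbr[a]:
                if b not in placed:
                    placed.add(b)
                    order.append(b)
                    queue.append(b)
        parents = {}
        placed = set(kept)
        for b in order:
            cand = [a for a in nbr[b] if a in placed]
            parents[b] = cand[0] if cand else None
            placed.add(b)
        return kept, order, parents

    def _bonded_terms_for(self, tmpl, b, placed):
        angles = [(i, j, k, key) for i, j, k, key in tmpl.angles
                  if b in (i, j, k) and all(x in placed or x == b for x in (i, j, k))]
        dihs = [(i, j, k, l, key) for i, j, k, l, key in tmpl.dihedrals
                if b in (i, j, k, l)
                and all(x in placed or x == b for x in (i, j, k, l))]
        return angles, dihs

    def _bond_length(self, tmpl, b, parent):
        for i, j, key in tmpl.bonds:
            if {i, j} == {b, parent}:
                term = self.ff.bond_terms[key]
                if term.fixed or not self.flexible_bonds:
                    return term.r0
                sig = math.sqrt(1.0 / (self.beta * term.k))
                rmax = term.r0 + 5.0 * sig
                while True:
                    r = self.rng.normal(term.r0, sig)
                    if r > 0 and self.rng.random() < (r / rmax) ** 2:
                        return r
        raise KeyError(f"no bond between {b} and {parent}")

    def _draw_direction(self, coords, tmpl, b, parent, placed, r,
                        max_batches: int = 40):
        """Direction from the bonded Boltzmann distribution via rejection
        sampling on uniform sphere directions (batched)."""
        angles, dihs = self._bonded_terms_for(tmpl, b, placed)
        offset = sum(self._dih_offsets[key] for *_ijk, key in dihs)
        K = 64
        for _ in range(max_batches):
            v = self.rng.normal(size=(K, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            cand = coords[parent] + r * v
            w = np.zeros(K)
            for i, j, k, key in angles:
                term = self.ff.angle_terms[key]
                if term.k is None:
                    continue
                pi_, pj_, pk_ = [cand if x == b else
                                 np.broadcast_to(coords[x], (K, 3))
                                 for x in (i, j, k)]
                th = _angle_vec(pi_, pj_, pk_)
                w += 0.5 * term.k * (th - term.theta0_rad) ** 2
            for i, j, k, l, key in dihs:
                pts = [cand if x == b else np.broadcast_to(coords[x], (K, 3))
                       for x in (i, j, k, l)]
                phi = _dihedral_vec(*pts)
                w += self.ff.dihedral_terms[key].energy(phi)
            w -= offset
            acc = self.rng.random(K) < np.exp(-self.beta * np.maximum(w, 0.0))
            idx = np.nonzero(acc)[0]
            if len(idx) > 0:
                return cand[idx[0]]
        # stiff degenerate case: return the best candidate seen
        return cand[int(np.argmin(w))]

    def _bead_ext_energy(self, m, b, xyz, coords_mol, placed_local):
        """External energy of one bead trial position: nonbonded with other
        molecules plus scaled intra terms with already-placed beads."""
        sl = self.slices[m]
        others = np.ones(self.snap.n_sites, dtype=bool)
        others[sl] = False
        pos_o = self.snap.coords[others]
        L = self.snap.box
        d = pos_o - xyz
        d -= L * np.round(d / L)
        r2 = (d**2).sum(axis=1)
        if np.any(r2 < R_MIN * R_MIN):
            return math.inf
        t_b = self.table.site_type[sl][b]
        t_o = self.table.site_type[others]
        mask = r2 <= self.ff.r_cut**2
        u = 0.0
        if mask.any():
            sig = self.table.sigma[t_b, t_o[mask]]
            eps = self.table.eps[t_b, t_o[mask]]
            s6 = (sig**2 / r2[mask]) ** 3
            uu = 4.0 * eps * (s6 * s6 - s6)
            if self.ff.lrc_mode == "shifted":
                xc6 = (sig / self.ff.r_cut) ** 6
                uu -= 4.0 * eps * (xc6 * xc6 - xc6)
            u += float(uu.sum())
            if self.table.has_charges:
                qb = self.table.charges[sl][b]
                if qb != 0.0:
                    r = np.sqrt(r2[mask])
                    u += COULOMB_KJ_A * qb * float(np.sum(
                        self.table.charges[others][mask]
                        * erfc(self.ewald.kappa * r) / r))
        qm = self.table.charges[sl]
        tm = self.table.site_type[sl]
        kappa = self.ewald.kappa if self.kvec is not None else 0.0
        tmpl = self.tmpls[m]
        for i, j, slj, scoul in self.table.intra_pairs(tmpl.name):
            if b not in (i, j):
                continue
            o = j if i == b else i
            if o not in placed_local:
                continue
            r = float(np.linalg.norm(coords_mol[o] - xyz))
            if r < R_MIN and (slj != 0.0 or scoul != 0.0):
                return math.inf
            if slj != 0.0:
                s = self.table.sigma[tm[b], tm[o]]
                e = self.table.eps[tm[b], tm[o]]
                x6 = (s / r) ** 6
                u += slj * 4.0 * e * (x6 * x6 - x6)
            if qm[b] != 0.0 and qm[o] != 0.0:
                if scoul != 0.0:
                    u += scoul * COULOMB_KJ_A * qm[b] * qm[o] / r
                if self.kvec is not None:
                    u -= COULOMB_KJ_A * qm[b] * qm[o] * float(erf(kappa * r)) / r
        return u

    def _grow(self, m, kept, order, parents, old_coords=None):
        """Grow (or retrace, when old_coords given) the regrown beads.

        Returns (coords, log Rosenbluth weight) or (None, -inf) on failure.
        """
        tmpl = self.tmpls[m]
        coords = self.snap.coords[self.slices[m]].copy()
        if old_coords is not None:
            grown_ref = old_coords
        placed = set(kept)
        logW = 0.0
        for idx, b in enumerate(order):
            parent = parents[b]
            nb_trials = self.schedule.n_first if parent is None else self.schedule.n_bead
            trials = np.empty((nb_trials, 3))
            for t in range(nb_trials):
                if old_coords is not None and t == 0:
                    trials[t] = grown_ref[b]
                    continue
                if parent is None:
                    trials[t] = self.rng.random(3) * self.snap.box
                else:
                    r = self._bond_length(tmpl, b, parent)
                    trials[t] = self._draw_direction(coords, tmpl, b, parent,
                                                     placed, r)
            u_ext = np.array([
                self._bead_ext_energy(m, b, trials[t], coords, placed)
                for t in range(nb_trials)
            ])
            finite = ~np.isinf(u_ext)
            if not finite.any():
                return None, -math.inf
            umin = float(u_ext[finite].min())
            w = np.where(finite, np.exp(-self.beta * (u_ext - umin)), 0.0)
            wsum = float(w.sum())
            logW += math.log(wsum / nb_trials) - self.beta * umin
            if old_coords is not None:
                chosen = 0
            else:
                chosen = int(self.rng.choice(nb_trials, p=w / wsum))
            coords[b] = trials[chosen]
            placed.add(b)
        return coords, logW

    def cbmc_regrow(self, m: int | None = None) -> tuple[bool, float]:
        if m is None:
            m = int(self.rng.integers(self.snap.n_molecules))
        tmpl = self.tmpls[m]
        if tmpl.rigidity == "fully_rigid":
            raise ValueError("regrowth needs a flexible or fixed-bond molecule")
        sl = self.slices[m]
        old = self.snap.coords[sl].copy()
        kept, order, parents = self._regrow_order(tmpl)
        new_coords, logW_new = self._grow(m, kept, order, parents)
        if new_coords is None:
            return False, 0.0
        _, logW_old = self._grow(m, kept, order, parents, old_coords=old)
        dS = self._delta_S(m, new_coords)
        du_recip = 0.0
        if dS is not None:
            du_recip = self._u_recip(self._S + dS) - self._u_recip()
        log_acc = logW_new - logW_old - self.beta * du_recip
        if math.log(max(self.rng.random(), 1e-300)) < log_acc:
            du = (self._mol_nb(m, new_coords) - self._mol_nb(m, old)
                  + self._mol_intra(m, new_coords) - self._mol_intra(m, old)
                  + du_recip)
            if math.isinf(du):
                return False, 0.0
            self.snap.coords[sl] = new_coords
            if dS is not None:
                self._S += dS
            self.u_total += du
            return True, du
        return False, 0.0

    # -- driver -------------------------------------------------------------

    def run_stage(self, n_mcc: int, npt: bool, adapt: bool,
                  sample_interval: int, T: float | None = None):
        """Run one stage; returns (samples dict of lists, counters)."""
        if T is not None:
            self.beta = 1.0 / (R_KJ * T)
        n = self.snap.n_molecules
        kinds = self.kinds
        counters = {k: [0, 0] for k in kinds + ["volume"]}
        window = {k: [0, 0] for k in kinds + ["volume"]}
        samples = {"mcc": [], "volume": [], "rho": [], "u": []}
        acc_rho = 0.0
        acc_n = 0.0
        mtot = float(self.table.masses.sum())
        for mcc in range(n_mcc):
            for _ in range(n):
                r = self.rng.random()
                if npt and r < self.schedule.p_volume:
                    kind = "volume"
                    ok, _du = self.volume_move()
                else:
                    kind = kinds[int(self.rng.integers(len(kinds)))]
                    if kind == "translate":
                        ok, _du = self.translate_move()
                    elif kind == "rotate":
                        ok, _du = self.rotate_move()
                    else:
                        ok, _du = self.cbmc_regrow()
                counters[kind][0] += 1
                counters[kind][1] += int(ok)
                window[kind][0] += 1
                window[kind][1] += int(ok)
                acc_rho += DENSITY_FACTOR * mtot / self.snap.box**3
                acc_n += 1.0
            if adapt and (mcc + 1) % self.schedule.adapt_interval == 0:
                self.schedule = adapt_max_displacements(
                    {k: tuple(v) for k, v in window.items()},
                    self.schedule, self.snap.box)
                window = {k: [0, 0] for k in window}
            if (mcc + 1) % sample_interval == 0:
                samples["mcc"].append(mcc + 1)
                samples["volume"].append(self.snap.box**3)
                samples["rho"].append(DENSITY_FACTOR * mtot / self.snap.box**3)
                samples["u"].append(self.u_total)
        return samples, {k: tuple(v) for k, v in counters.items()}, acc_rho, acc_n


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _angle(p0, p1, p2) -> float:
    a = p0 - p1
    b = p2 - p1
    c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.acos(max(-1.0, min(1.0, c)))


def _angle_vec(p0, p1, p2):
    a = p0 - p1
    b = p2 - p1
    c = (a * b).sum(axis=1) / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
    return np.arccos(np.clip(c, -1.0, 1.0))


def _dihedral_vec(p0, p1, p2, p3):
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    m = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=1)
    y = (m * n2).sum(axis=1)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# staged drivers
# ---------------------------------------------------------------------------

def _is_fast_eligible(tmpl: MoleculeTemplate, ff: ForceField) -> bool:
    return tmpl.n_sites == 1 and all(
        ff.atom_types[t].charge == 0.0 for t in tmpl.site_types)


def run_npt(sp: StatePoint, seed: int = 0,
            schedule: MoveSchedule | None = None,
            plan: StagePlan | None = None,
            ff: ForceField | None = None,
            templates: dict[str, MoleculeTemplate] | None = None,
            snap: Snapshot | None = None,
            lrc_mode: str | None = None,
            flexible_bonds: bool = False,
            use_fast: bool | str = "auto",
            label: str = "") -> TrajectoryRecord:
    """Full staged NpT MC run for one replicate; reproducible given ``seed``.

    Stage seeds are re-keyed deterministically from ``seed``; the fast numba
    path is used automatically for single-site uncharged models unless
    ``use_fast=False``.
    """
    templates = templates or builtin_models()
    tmpl = templates[sp.model]
    ff = ff or builtin_forcefields()[tmpl.ff_name]
    ff = ff.replace(r_cut=sp.r_cut, **({"lrc_mode": lrc_mode} if lrc_mode else {}))
    schedule = schedule or MoveSchedule.default_for(sp, tmpl, ff)
    plan = plan or StagePlan()
    snap = snap or build_lattice_config(sp, seed)
    fast = _is_fast_eligible(tmpl, ff) if use_fast == "auto" else bool(use_fast)
    if fast and not _is_fast_eligible(tmpl, ff):
        raise ValueError("fast path requires a single-site uncharged model")
    if fast:
        return _run_npt_fast(sp, seed, schedule, plan, ff, tmpl, snap, label)
    return _run_npt_general(sp, seed, schedule, plan, ff, templates, snap,
                            flexible_bonds, label)


def _equilibrated(rho_tail: np.ndarray) -> bool:
    from .analysis import detect_equilibration

    if len(rho_tail) < 10:
        return True
    start, g, neff = detect_equilibration(np.asarray(rho_tail))
    frac = (len(rho_tail) - start) / len(rho_tail)
    return neff >= 100 or frac >= 0.8


def _run_npt_fast(sp, seed, schedule, plan, ff, tmpl, snap, label):
    mode = {"hard": mc_fast.MODE_HARD, "shifted": mc_fast.MODE_SHIFTED,
            "tail": mc_fast.MODE_TAIL}[ff.lrc_mode]
    at = ff.atom_types[tmpl.site_types[0]]
    sigma, eps = at.lj.sigma, at.lj.epsilon
    rc = ff.r_cut
    x3 = (sigma / rc) ** 3
    x9 = x3**3
    tail_coef = (8.0 * math.pi / 3.0) * sp.N**2 * eps * sigma**3 * (x9 / 3.0 - x3)
    rho_factor = DENSITY_FACTOR * sp.N * at.mass
    p_e = sp.p * KPA_A3_TO_KJMOL
    pos = snap.coords.copy()
    L = snap.box
    stage_seeds = np.random.SeedSequence(seed).generate_state(16) % (2**31)
    samples = {"mcc": [], "volume": [], "rho": [], "u": []}
    labels: list[str] = []
    counters = {"translate": [0, 0], "volume": [0, 0]}
    d_trans, d_lnv = schedule.d_trans, schedule.d_lnv
    prod_acc_rho = prod_acc_n = 0.0
    mcc_offset = 0
    si = 0

    def _stage(name, n_mcc, T, npt, adapt):
        nonlocal pos, L, d_trans, d_lnv, mcc_offset, si, prod_acc_rho, prod_acc_n
        if n_mcc <= 0:
            return
        beta = 1.0 / (R_KJ * T)
        (pos, L, _u, sv, su, a_rho, a_n, at_t, ac_t, at_v, ac_v,
         d_trans, d_lnv) = mc_fast.npt_lj_stage(
            pos, L, beta, p_e if npt else 0.0, n_mcc, plan.sample_interval,
            sigma, eps, rc, mode, tail_coef if mode == mc_fast.MODE_TAIL else 0.0,
            d_trans, d_lnv, schedule.p_volume if npt else 0.0,
            adapt, schedule.target_acceptance, schedule.adapt_interval,
            rho_factor, int(stage_seeds[si]))
        si += 1
        counters["translate"][0] += at_t
        counters["translate"][1] += ac_t
        counters["volume"][0] += at_v
        counters["volume"][1] += ac_v
        k = len(sv)
        samples["mcc"].extend((mcc_offset + (np.arange(k) + 1)
                               * plan.sample_interval).tolist())
        samples["volume"].extend(sv.tolist())
        samples["rho"].extend((rho_factor / sv).tolist())
        samples["u"].extend(su.tolist())
        labels.extend([name] * k)
        mcc_offset += n_mcc
        if name == "production":
            prod_acc_rho += a_rho
            prod_acc_n += a_n

    _stage("melt", plan.melt_mcc, plan.melt_T, False, True)
    _stage("cool", plan.cool_mcc, sp.T, False, True)
    for block in range(plan.max_equil_blocks):
        _stage("equilibration", plan.equil_block_mcc, sp.T, True, True)
        ncheck = plan.equil_check_mcc // plan.sample_interval
        rho_tail = np.array(samples["rho"][-ncheck:])
        if _equilibrated(rho_tail):
            break
    _stage("production", plan.production_mcc, sp.T, True, False)

    final_schedule = dc_replace(schedule, d_trans=d_trans, d_lnv=d_lnv)
    return TrajectoryRecord(
        model=sp.model, sp=sp, seed=seed,
        mcc=np.array(samples["mcc"]), volume=np.array(samples["volume"]),
        rho=np.array(samples["rho"]), u_total=np.array(samples["u"]),
        stage_labels=labels, counters={k: tuple(v) for k, v in counters.items()},
        prod_acc_rho=prod_acc_rho, prod_acc_n=prod_acc_n, final_box=L,
        final_schedule=final_schedule, method="mc", label=label)


def _run_npt_general(sp, seed, schedule, plan, ff, templates, snap,
                     flexible_bonds, label):
    engine = GeneralNptMC(snap, ff, sp, schedule, seed, templates,
                          flexible_bonds)
    samples = {"mcc": [], "volume": [], "rho": [], "u": []}
    labels: list[str] = []
    counters: dict[str, list[int]] = {}
    prod_acc_rho = prod_acc_n = 0.0
    mcc_offset = 0

    def _merge(c):
        for k, v in c.items():
            counters.setdefault(k, [0, 0])
            counters[k][0] += v[0]
            counters[k][1] += v[1]

    def _stage(name, n_mcc, T, npt, adapt):
        nonlocal mcc_offset, prod_acc_rho, prod_acc_n
        if n_mcc <= 0:
            return
        s, c, a_rho, a_n = engine.run_stage(n_mcc, npt, adapt,
                                            plan.sample_interval, T=T)
        _merge(c)
        samples["mcc"].extend([mcc_offset + m for m in s["mcc"]])
        samples["volume"].extend(s["volume"])
        samples["rho"].extend(s["rho"])
        samples["u"].extend(s["u"])
        labels.extend([name] * len(s["mcc"]))
        mcc_offset += n_mcc
        if name == "production":
            prod_acc_rho += a_rho
            prod_acc_n += a_n

    _stage("melt", plan.melt_mcc, plan.melt_T, False, True)
    _stage("cool", plan.cool_mcc, sp.T, False, True)
    for _ in range(plan.max_equil_blocks):
        _stage("equilibration", plan.equil_block_mcc, sp.T, True, True)
        ncheck = plan.equil_check_mcc // plan.sample_interval
        if _equilibrated(np.array(samples["rho"][-ncheck:])):
            break
    _stage("production", plan.production_mcc, sp.T, True, False)
    return TrajectoryRecord(
        model=sp.model, sp=sp, seed=seed,
        mcc=np.array(samples["mcc"]), volume=np.array(samples["volume"]),
        rho=np.array(samples["rho"]), u_total=np.array(samples["u"]),
        stage_labels=labels, counters={k: tuple(v) for k, v in counters.items()},
        prod_acc_rho=prod_acc_rho, prod_acc_n=prod_acc_n,
        final_box=engine.snap.box, final_schedule=engine.schedule,
        method="mc", label=label)


def run_cutoff_scan(sp: StatePoint, r_cuts: list[float], mode: str,
                    seeds: list[int], plan: StagePlan | None = None,
                    schedule: MoveSchedule | None = None):
    """Replicate MC campaigns over cutoff radii.

    Returns a DataFrame with mean density, 95% CI, and asymptotic errors
    (percent deviation from the largest cutoff's density).
    """
    import pandas as pd

    from .analysis import replicate_statistics

    rows = []
    for rc in sorted(r_cuts):
        sp_rc = dc_replace(sp, r_cut=rc)
        runs = [run_npt(sp_rc, seed=s, plan=plan, schedule=schedule,
                        lrc_mode=mode) for s in seeds]
        stats = replicate_statistics(runs)
        rows.append({"r_cut": rc, "rho_mean": stats.mean, "ci95": stats.ci95,
                     "n_replicates": len(seeds)})
    df = pd.DataFrame(rows)
    ref_rho = df["rho_mean"].iloc[-1]   # rows sorted by r_cut: last = largest
    df["asymptotic_error_pct"] = (df["rho_mean"] - ref_rho) / ref_rho * 100.0
    return df
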