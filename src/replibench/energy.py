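"""Single-point potential energy with full decomposition and virial.

Lennard-Jones interactions support three cutoff treatments: ``hard``
(truncated, unshifted), ``shifted`` (the pair potential is shifted up by the
negative of its value at r_cut, leaving forces unchanged), and ``tail``
(truncated plus analytic energy/pressure corrections assuming unit pair
correlation beyond the cutoff).  Coulomb interactions use tinfoil-boundary
Ewald summation.  All pair sums are accumulated in a fixed order (sorted site
index pairs, chunked rows) so a given snapshot always yields a bit-identical
report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, erfc

from .configio import Snapshot
from .constants import COULOMB_KJ_A, KJMOL_A3_TO_KPA, R_KJ
from .ffparams import ForceField
from .models import MoleculeTemplate, builtin_forcefields, builtin_models

__all__ = [
    "EnergyReport",
    "EwaldSettings",
    "PairTable",
    "lj_pair_energy",
    "tail_corrections",
    "ewald_energy",
    "bonded_energy",
    "single_point",
    "compare_single_points",
]

#: hard inner cutoff: nonbonded distances below this yield a +inf sentinel
R_MIN = 1.0


@dataclass
class EnergyReport:
    """Decomposed potential energy (kJ/mol) plus virial pressure (kPa)."""

    lj_pair: float = 0.0
    lj_tail: float = 0.0
    lj_shift_applied: bool = False
    coulomb_real: float = 0.0
    coulomb_reciprocal: float = 0.0
    coulomb_self: float = 0.0
    coulomb_exclusion_correction: float = 0.0
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    intra_nonbonded: float = 0.0
    virial_pressure: float = float("nan")

    @property
    def components(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "lj_pair", "lj_tail", "coulomb_real", "coulomb_reciprocal",
                "coulomb_self", "coulomb_exclusion_correction", "bond",
                "angle", "dihedral", "intra_nonbonded",
            )
        }

    @property
    def total(self) -> float:
        return math.fsum(self.components.values())


@dataclass
class EwaldSettings:
    """kappa in Å^-1; kmax per axis; optional relative accuracy target."""

    kappa: float
    kmax: int
    accuracy: float | None = None
    boundary: str = "tinfoil"

    def __post_init__(self):
        if self.kappa <= 0 or self.kmax < 1:
            raise ValueError("kappa must be > 0 and kmax >= 1")

    @classmethod
    def from_system(cls, r_cut: float, box: float,
                    accuracy: float | None = None) -> "EwaldSettings":
        """Default derivation: kappa = 3.6 / r_cut, kmax = int(kappa L) + 1."""
        kappa = 3.6 / r_cut
        return cls(kappa=kappa, kmax=int(kappa * box) + 1, accuracy=accuracy)


def lj_pair_energy(r, sigma: float, eps: float, r_cut: float, mode: str = "hard"):
    """12-6 Lennard-Jones pair energy under a cutoff treatment.

    ``shifted`` subtracts the pair's value at r_cut inside the cutoff; ``hard``
    and ``tail`` return the bare truncated value (the tail correction is a
    system-level term, see :func:`tail_corrections`).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    x6 = (sigma / r) ** 6
    u = 4.0 * eps * (x6 * x6 - x6)
    if mode == "shifted":
        xc6 = (sigma / r_cut) ** 6
        u = u - 4.0 * eps * (xc6 * xc6 - xc6)
    out = np.where(r <= r_cut, u, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# pair table: precomputed per-snapshot interaction arrays
# ---------------------------------------------------------------------------

class PairTable:
    """Precomputed per-site type indices, LJ matrices, charges and
    intramolecular scale factors for one (snapshot, force field) pairing."""

    def __init__(self, snap: Snapshot, ff: ForceField,
                 templates: dict[str, MoleculeTemplate] | None = None):
        templates = templates or builtin_models()
        self.ff = ff
        self.templates = templates
        type_names: list[str] = []
        site_type = np.empty(snap.n_sites, dtype=int)
        charges = np.empty(snap.n_sites)
        masses = np.empty(snap.n_sites)
        k = 0
        self.mol_tmpl = [templates[t] for t in snap.mol_templates]
        for tmpl in self.mol_tmpl:
            for t in tmpl.site_types:
                if t not in type_names:
                    type_names.append(t)
                site_type[k] = type_names.index(t)
                charges[k] = ff.atom_types[t].charge
                masses[k] = ff.atom_types[t].mass
                k += 1
        if k != snap.n_sites:
            raise ValueError("molecule_index inconsistent with template site counts")
        nt = len(type_names)
        sig = np.empty((nt, nt))
        eps = np.empty((nt, nt))
        for a in range(nt):
            for b in range(nt):
                sig[a, b], eps[a, b] = ff.pair_params(type_names[a], type_names[b])
        self.type_names = type_names
        self.site_type = site_type
        self.sigma = sig
        self.eps = eps
        self.charges = charges
        self.masses = masses
        self.mol_id = snap.mol_index.copy()
        self.has_charges = bool(np.any(charges != 0.0))
        # per-template intramolecular pair scale factors
        self._intra: dict[str, list[tuple[int, int, float, float]]] = {}
        for tname in set(snap.mol_templates):
            tmpl = templates[tname]
            sep = tmpl.bond_separations()
            pairs = []
            for i in range(tmpl.n_sites):
                for j in range(i + 1, tmpl.n_sites):
                    slj, scoul = ff.nonbonded_scales(int(sep[i, j]))
                    pairs.append((i, j, slj, scoul))
            self._intra[tname] = pairs

    def intra_pairs(self, tname: str):
        return self._intra[tname]


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def tail_corrections(snap: Snapshot, ff: ForceField,
                     templates: dict[str, MoleculeTemplate] | None = None,
                     table: PairTable | None = None) -> tuple[float, float]:
    """Analytic LJ tail corrections (U_tail in kJ/mol, p_tail in kPa).

    U_tail = (8 pi / 3V) sum_ab N_a N_b eps sigma^3 [x^9/3 - x^3],
    p_tail = (16 pi / 3V^2) sum_ab N_a N_b eps sigma^3 [2x^9/3 - x^3] with
    x = sigma/r_cut, summed over all type pairs (like pairs counted N_a N_b,
    the uniform-fluid convention).  Returns (0, 0) unless lrc_mode == 'tail'.
    """
    if ff.lrc_mode != "tail":
        return 0.0, 0.0
    table = table or PairTable(snap, ff, templates)
    counts = np.bincount(table.site_type, minlength=len(table.type_names)).astype(float)
    V = snap.box**3
    rc = ff.r_cut
    u = 0.0
    w = 0.0
    for a in range(len(counts)):
        for b in range(len(counts)):
            e = table.eps[a, b]
            if e == 0.0:
                continue
            s = table.sigma[a, b]
            x3 = (s / rc) ** 3
            x9 = x3**3
            pref = counts[a] * counts[b] * e * s**3
            u += pref * (x9 / 3.0 - x3)
            w += pref * (2.0 * x9 / 3.0 - x3)
    u_tail = (8.0 * math.pi / (3.0 * V)) * u
    p_tail = (16.0 * math.pi / (3.0 * V * V)) * w * KJMOL_A3_TO_KPA
    return u_tail, p_tail


# ---------------------------------------------------------------------------
# Ewald summation
# ---------------------------------------------------------------------------

def _kvectors(kmax: int, L: float):
    """Half-space integer triples with 0 < |n|^2 <= kmax^2, plus weights 2
    (full space recovered by symmetry)."""
    rng = np.arange(-kmax, kmax + 1)
    nx, ny, nz = np.meshgrid(rng, rng, rng, indexing="ij")
    n = np.column_stack([nx.ravel(), ny.ravel(), nz.ravel()])
    n2 = (n**2).sum(axis=1)
    mask = (n2 > 0) & (n2 <= kmax * kmax)
    # half space: first nonzero component positive
    first = np.where(n[:, 0] != 0, np.sign(n[:, 0]),
                     np.where(n[:, 1] != 0, np.sign(n[:, 1]), np.sign(n[:, 2])))
    mask &= first > 0
    return n[mask]


def ewald_energy(snap: Snapshot, ff: ForceField,
                 settings: EwaldSettings | None = None,
                 templates: dict[str, MoleculeTemplate] | None = None,
                 table: PairTable | None = None) -> dict[str, float]:
    """Tinfoil-boundary Ewald sum; returns the four components in kJ/mol.

    Real space: erfc-screened, truncated at r_cut, intermolecular pairs only.
    Reciprocal: k-vectors with |n| <= kmax.  Self: standard.  Exclusion
    correction: the erf-screened interaction is subtracted for every
    intramolecular pair at its true (bonded) separation, so that the Ewald
    machinery contributes nothing net to intramolecular electrostatics (the
    scaled 1-4 bare Coulomb term lives in the bonded/intra report field).
    """
    table = table or PairTable(snap, ff, templates)
    q = table.charges
    if not table.has_charges:
        return {"real": 0.0, "reciprocal": 0.0, "self": 0.0, "exclusion": 0.0}
    if abs(q.sum()) > 1e-9:
        raise ValueError(f"non-neutral system (net charge {q.sum():g} e)")
    L = snap.box
    if settings is None:
        settings = EwaldSettings.from_system(ff.r_cut, L)
    kappa = settings.kappa

    # real space (chunked, intermolecular only, minimum image)
    pos = snap.coords
    n = snap.n_sites
    real = 0.0
    chunk = 512
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        d = pos[i0:i1, None, :] - pos[None, :, :]
        d = _min_image(d, L)
        r = np.sqrt((d**2).sum(axis=-1))
        idx_i = np.arange(i0, i1)[:, None]
        idx_j = np.arange(n)[None, :]
        mask = (idx_j > idx_i) & (table.mol_id[idx_j] != table.mol_id[idx_i]) \
            & (r <= ff.r_cut)
        if mask.any():
            rr = r[mask]
            real += float(np.sum(q[idx_i.repeat(n, 1)[mask]]
                                 * q[idx_j.repeat(i1 - i0, 0)[mask]]
                                 * erfc(kappa * rr) / rr))
    real *= COULOMB_KJ_A

    recip = _ewald_reciprocal(pos, q, L, kappa, settings.kmax)
    if settings.accuracy is not None:
        kmax = settings.kmax
        while True:
            kmax += 1
            new = _ewald_reciprocal(pos, q, L, kappa, kmax)
            if abs(new - recip) <= settings.accuracy * max(abs(new), 1e-300):
                recip = new
                break
            recip = new

    self_term = -COULOMB_KJ_A * kappa / math.sqrt(math.pi) * float(np.sum(q * q))

    excl = 0.0
    for sl, tmpl in zip(snap.mol_slices(), table.mol_tmpl):
        p = pos[sl]
        qm = q[sl]
        for i, j, _slj, _sc in table.intra_pairs(tmpl.name):
            r = float(np.linalg.norm(p[j] - p[i]))
            excl -= COULOMB_KJ_A * qm[i] * qm[j] * float(erf(kappa * r)) / r
    return {"real": real, "reciprocal": recip, "self": self_term, "exclusion": excl}


def _ewald_reciprocal(pos: np.ndarray, q: np.ndarray, L: float,
                      kappa: float, kmax: int) -> float:
    V = L**3
    nvec = _kvectors(kmax, L)
    k = 2.0 * math.pi * nvec / L              # (nk, 3)
    k2 = (k**2).sum(axis=1)
    phase = pos @ k.T                          # (n, nk)
    S = (q[:, None] * np.exp(1j * phase)).sum(axis=0)
    A = np.exp(-k2 / (4.0 * kappa * kappa)) / k2
    # factor 2 restores the full k-space from the half space
    return COULOMB_KJ_A * (2.0 * math.pi / V) * 2.0 * float(np.sum(A * np.abs(S) ** 2))


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _angle(p0, p1, p2) -> float:
    a = p0 - p1
    b = p2 - p1
    c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.acos(max(-1.0, min(1.0, c)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Dihedral in radians, trans = pi (the TraPPE/OPLS sign convention)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m, n2))
    return math.atan2(y, x)


def bonded_energy(snap: Snapshot, ff: ForceField,
                  templates: dict[str, MoleculeTemplate] | None = None,
                  table: PairTable | None = None) -> dict[str, float]:
    """(bond, angle, dihedral, intra_nonbonded) in kJ/mol.

    Harmonic bonds are skipped when fixed; intramolecular nonbonded pairs use
    the force field's exclusion policy (bare Coulomb, no cutoff, true
    separations).
    """
    table = table or PairTable(snap, ff, templates)
    out = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0, "intra_nonbonded": 0.0}
    for sl, tmpl in zip(snap.mol_slices(), table.mol_tmpl):
        p = snap.coords[sl]
        for i, j, key in tmpl.bonds:
            term = ff.bond_terms[key]
            if term.fixed:
                continue
            r = float(np.linalg.norm(p[j] - p[i]))
            out["bond"] += 0.5 * term.k * (r - term.r0) ** 2
        for i, j, k, key in tmpl.angles:
            term = ff.angle_terms[key]
            if term.k is None:
                continue
            th = _angle(p[i], p[j], p[k])
            out["angle"] += 0.5 * term.k * (th - term.theta0_rad) ** 2
        for i, j, k, l, key in tmpl.dihedrals:
            phi = dihedral_angle(p[i], p[j], p[k], p[l])
            out["dihedral"] += float(ff.dihedral_terms[key].energy(phi))
        qm = table.charges[sl]
        tmask = table.site_type[sl]
        for i, j, slj, scoul in table.intra_pairs(tmpl.name):
            if slj == 0.0 and scoul == 0.0:
                continue
            r = float(np.linalg.norm(p[j] - p[i]))
            if slj != 0.0:
                s = table.sigma[tmask[i], tmask[j]]
                e = table.eps[tmask[i], tmask[j]]
                x6 = (s / r) ** 6
                out["intra_nonbonded"] += slj * 4.0 * e * (x6 * x6 - x6)
            if scoul != 0.0:
                out["intra_nonbonded"] += scoul * COULOMB_KJ_A * qm[i] * qm[j] / r
    return out


# ---------------------------------------------------------------------------
# full single-point evaluation
# ---------------------------------------------------------------------------

def _lj_inter(snap: Snapshot, ff: ForceField, table: PairTable
              ) -> tuple[float, float, bool]:
    """Intermolecular LJ energy + virial sum r·(-du/dr); returns
    (energy, virial, overlap_flag).  Chunked over sorted row blocks."""
    pos = snap.coords
    n = snap.n_sites
    L = snap.box
    rc = ff.r_cut
    mode = ff.lrc_mode
    sig = table.sigma[table.site_type][:, table.site_type]
    eps = table.eps[table.site_type][:, table.site_type]
    shift = np.zeros_like(sig)
    if mode == "shifted":
        xc6 = (sig / rc) ** 6
        shift = 4.0 * eps * (xc6 * xc6 - xc6)
    energy = 0.0
    virial = 0.0
    overlap = False
    chunk = 512
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        d = pos[i0:i1, None, :] - pos[None, :, :]
        d = _min_image(d, L)
        r2 = (d**2).sum(axis=-1)
        idx_i = np.arange(i0, i1)[:, None]
        idx_j = np.arange(n)[None, :]
        inter = (idx_j > idx_i) & (table.mol_id[None, :] != table.mol_id[i0:i1, None])
        if np.any(inter & (r2 < R_MIN * R_MIN)):
            overlap = True
        mask = inter & (r2 <= rc * rc)
        if not mask.any():
            continue
        r2m = r2[mask]
        s6 = (sig[i0:i1][mask] ** 2 / r2m) ** 3
        e6 = eps[i0:i1][mask]
        u = 4.0 * e6 * (s6 * s6 - s6)
        if mode == "shifted":
            u = u - shift[i0:i1][mask]
        energy += float(u.sum())
        virial += float(np.sum(24.0 * e6 * (2.0 * s6 * s6 - s6)))
    return energy, virial, overlap


def single_point(snap: Snapshot, ff: ForceField,
                 templates: dict[str, MoleculeTemplate] | None = None,
                 ewald_settings: EwaldSettings | None = None) -> EnergyReport:
    """Full decomposed potential energy and virial pressure for a snapshot.

    Deterministic: the same snapshot always produces a bit-identical report.
    The virial pressure uses the molecular kinetic convention
    P = (N_mol k_B T + W/3)/V at the state-point temperature left implicit;
    here only the configurational part W/3V + p_tail is reported plus the
    ideal term evaluated with T = 0 omitted — see ``virial_pressure_kpa`` for
    the T-aware helper.  Reciprocal-space Coulomb virial is not included.
    """
    if snap.box < 2.0 * ff.r_cut:
        raise ValueError(
            f"box edge {snap.box:.2f} Å below 2*r_cut = {2 * ff.r_cut:.2f} Å"
        )
    templates = templates or builtin_models()
    table = PairTable(snap, ff, templates)
    rep = EnergyReport()
    lj, w, overlap = _lj_inter(snap, ff, table)
    rep.lj_pair = lj
    rep.lj_shift_applied = ff.lrc_mode == "shifted"
    u_tail, p_tail = tail_corrections(snap, ff, templates, table=table)
    rep.lj_tail = u_tail
    if table.has_charges:
        ew = ewald_energy(snap, ff, ewald_settings, templates, table=table)
        rep.coulomb_real = ew["real"]
        rep.coulomb_reciprocal = ew["reciprocal"]
        rep.coulomb_self = ew["self"]
        rep.coulomb_exclusion_correction = ew["exclusion"]
    b = bonded_energy(snap, ff, templates, table=table)
    rep.bond = b["bond"]
    rep.angle = b["angle"]
    rep.dihedral = b["dihedral"]
    rep.intra_nonbonded = b["intra_nonbonded"]
    V = snap.box**3
    rep.virial_pressure = (w / 3.0 / V) * KJMOL_A3_TO_KPA + p_tail
    if overlap:
        rep.lj_pair = float("inf")
    return rep


def virial_pressure_kpa(rep: EnergyReport, n_molecules: int, T: float,
                        volume: float) -> float:
    """Molecular-convention virial pressure including the ideal-gas kinetic
    term: P = N_mol k_B T / V + configurational part."""
    return n_molecules * R_KJ * T / volume * KJMOL_A3_TO_KPA + rep.virial_pressure


def compare_single_points(reports: list[EnergyReport], labels: list[str] | None = None):
    """Relative-error table across reports of the same system.

    Per report: (U - Ubar)/Ubar (displayed x1e5) plus per-component deltas
    against the component means.
    """
    import pandas as pd

    if len(reports) < 2:
        raise ValueError("need at least two reports")
    labels = labels or [f"report{i}" for i in range(len(reports))]
    totals = np.array([r.total for r in reports])
    ubar = totals.mean()
    rows = []
    comp_means = {
        k: np.mean([r.components[k] for r in reports]) for k in reports[0].components
    }
    for lab, r in zip(labels, reports):
        row = {"label": lab, "total": r.total,
               "rel_error_x1e5": (r.total - ubar) / ubar * 1e5}
        for k, v in r.components.items():
            row[f"d_{k}"] = v - comp_means[k]
        rows.append(row)
    return pd.DataFrame(rows)
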