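"""The five benchmark molecular models and their study state points.

Models: single-site united-atom methane, five-site united-atom n-pentane and
six-site rigid benzene (TraPPE-UA), rigid three-site SPC/E water, and the
nine-site all-atom OPLS ethanol.  Site masses are composed from IUPAC standard
atomic weights and stored with the force fields so they are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .constants import DENSITY_FACTOR, R_KJ
from .ffparams import (
    AngleTerm,
    AtomType,
    BerendsenAB,
    BondTerm,
    DihedralTerm,
    ForceField,
    LJParameters,
    spce_from_AB,
)

__all__ = [
    "MoleculeTemplate",
    "StatePoint",
    "builtin_models",
    "builtin_forcefields",
    "builtin_state_points",
    "scaled_state_point",
    "load_shipped_forcefield",
    "SPCE_AB",
]

KCAL = 4.184  # kJ per kcal

#: Berendsen's original SPC/E A/B constants
SPCE_AB = BerendsenAB(A=0.37122, B=0.3428)

RIGIDITIES = ("point", "fully_rigid", "fixed_bonds", "flexible")


@dataclass
class MoleculeTemplate:
    """Molecular topology + reference geometry.

    ``bonds``/``angles``/``dihedrals`` hold site-index tuples plus a key into
    the force field's term tables.  ``reference_coords`` is the equilibrium
    internal geometry (Å) used for rigid placement and constraint projection.
    """

    name: str
    ff_name: str
    site_types: list[str]
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    angles: list[tuple[int, int, int, str]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    rigidity: str = "flexible"
    reference_coords: np.ndarray | None = None
    rough_density: float = 500.0   # kg/m^3, used only for box-size estimates

    def __post_init__(self):
        if self.rigidity not in RIGIDITIES:
            raise ValueError(f"rigidity must be one of {RIGIDITIES}")

    @property
    def n_sites(self) -> int:
        return len(self.site_types)

    def masses(self, ff: ForceField) -> np.ndarray:
        return np.array([ff.atom_types[t].mass for t in self.site_types])

    def charges(self, ff: ForceField) -> np.ndarray:
        return np.array([ff.atom_types[t].charge for t in self.site_types])

    def molar_mass(self, ff: ForceField) -> float:
        return float(self.masses(ff).sum())

    def bond_separations(self) -> np.ndarray:
        """Bond-graph separation matrix: 1-2 neighbors -> 2, 1-3 -> 3, etc.
        (diagonal 1, unreachable -> large)."""
        n = self.n_sites
        dist = np.full((n, n), 9999, dtype=int)
        np.fill_diagonal(dist, 0)
        for i, j, _ in self.bonds:
            dist[i, j] = dist[j, i] = 1
        # Floyd-Warshall; molecules are tiny
        for k in range(n):
            dist = np.minimum(dist, dist[:, k][:, None] + dist[k][None, :])
        return dist + 1  # convention: bonded neighbors are "1-2" -> 2

    def connected(self) -> bool:
        return bool((self.bond_separations() < 9999).all()) if self.n_sites > 1 else True


@dataclass(frozen=True)
class StatePoint:
    """One row of the study conditions."""

    model: str
    N: int
    T: float       # K
    p: float       # kPa
    r_cut: float   # Å

    def __post_init__(self):
        if self.N <= 0 or self.T <= 0 or self.p <= 0 or self.r_cut <= 0:
            raise ValueError("N, T, p, r_cut must all be positive")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _zmat_dihedral(a, b, c, r, theta, phi):
    """Standard NeRF placement: new atom bonded to a, angle with b, dihedral with c."""
    ba = a - b
    ba /= np.linalg.norm(ba)
    cb = b - c
    n = np.cross(cb, ba)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # collinear frame; pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0]) if abs(ba[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(ba, ref)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, ba)
    d = np.array(
        [-r * math.cos(theta),
         r * math.sin(theta) * math.cos(phi),
         r * math.sin(theta) * math.sin(phi)]
    )
    return a + d[0] * ba + d[1] * m + d[2] * n


def _build_zmat(entries):
    """entries: list of (bond_to, r, angle_to, theta, dih_to, phi); first entry ignored."""
    coords: list[np.ndarray] = [np.zeros(3)]
    for e in entries:
        bond_to, r, angle_to, theta, dih_to, phi = e
        if angle_to < 0:
            coords.append(coords[bond_to] + np.array([r, 0.0, 0.0]))
        elif dih_to < 0:
            a, b = coords[bond_to], coords[angle_to]
            th = math.radians(theta)
            ab = (b - a) / np.linalg.norm(b - a)
            perp = np.cross(ab, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-12:
                perp = np.cross(ab, np.array([0.0, 1.0, 0.0]))
            perp /= np.linalg.norm(perp)
            coords.append(a + r * (math.cos(th) * ab + math.sin(th) * perp))
        else:
            coords.append(
                _zmat_dihedral(coords[bond_to], coords[angle_to], coords[dih_to],
                               r, math.radians(theta), math.radians(phi))
            )
    out = np.array(coords)
    return out - out.mean(axis=0)


# ---------------------------------------------------------------------------
# built-in force fields
# ---------------------------------------------------------------------------

def builtin_forcefields() -> dict[str, ForceField]:
    """The three force fields used by the five models, in internal units.

    TraPPE-UA well depths are published as eps/k_B in K and converted here with
    the frozen constants; OPLS values are published in kcal/mol (converted with
    the thermochemical calorie); SPC/E LJ parameters are the full-double-
    precision conversion of Berendsen's original A/B constants.
    """
    spce_lj = spce_from_AB(SPCE_AB, source_label="original-HP")

    trappe = ForceField(
        name="TraPPE-UA",
        atom_types={
            "CH4": AtomType(LJParameters(3.73, 148.0 * R_KJ, "TraPPE-UA"), 0.0, 16.043),
            "CH3": AtomType(LJParameters(3.75, 98.0 * R_KJ, "TraPPE-UA"), 0.0, 15.035),
            "CH2": AtomType(LJParameters(3.95, 46.0 * R_KJ, "TraPPE-UA"), 0.0, 14.027),
            "CHar": AtomType(LJParameters(3.695, 50.5 * R_KJ, "TraPPE-UA"), 0.0, 13.019),
        },
        bond_terms={
            "CC": BondTerm(r0=1.54),         # fixed length
            "CCar": BondTerm(r0=1.40),       # aromatic, rigid body
        },
        angle_terms={
            "CCC": AngleTerm(theta0=114.0, k=62500.0 * R_KJ),
        },
        dihedral_terms={
            "CCCC": DihedralTerm(c0=0.0, c1=355.03 * R_KJ, c2=-68.19 * R_KJ,
                                 c3=791.32 * R_KJ),
        },
        # LJ and Coulomb fully excluded for 1-2/1-3/1-4; unscaled at 1-5+
        exclusion_policy={2: (0.0, 0.0), 3: (0.0, 0.0), 4: (0.0, 0.0)},
        mixing_rule="lorentz",
        r_cut=14.0,
        lrc_mode="tail",
        provenance="10.1021/jp972543+ (alkanes); 10.1021/jp001044x (aromatics); "
                   "eps/k_B in K, sigma in Angstrom, fixed C-C bonds",
    )

    spce = ForceField(
        name="SPC/E",
        atom_types={
            "OW": AtomType(spce_lj, -0.8476, 15.999),
            "HW": AtomType(LJParameters(1.0, 0.0, "no-LJ"), 0.4238, 1.008),
        },
        bond_terms={"OH": BondTerm(r0=1.0)},
        angle_terms={"HOH": AngleTerm(theta0=109.47)},
        exclusion_policy={2: (0.0, 0.0), 3: (0.0, 0.0)},
        mixing_rule="lorentz",
        r_cut=9.0,
        lrc_mode="tail",
        provenance="10.1021/j100308a038; LJ converted from A=0.37122 (kJ/mol)^(1/6) nm, "
                   "B=0.3428 (kJ/mol)^(1/12) nm at full double precision",
    )

    opls = ForceField(
        name="OPLS-AA-ethanol",
        atom_types={
            "CT3": AtomType(LJParameters(3.50, 0.066 * KCAL, "OPLS-AA"), -0.18, 12.011),
            "CT2": AtomType(LJParameters(3.50, 0.066 * KCAL, "OPLS-AA"), 0.145, 12.011),
            "HC": AtomType(LJParameters(2.50, 0.030 * KCAL, "OPLS-AA"), 0.06, 1.008),
            "OH": AtomType(LJParameters(3.12, 0.170 * KCAL, "OPLS-AA"), -0.683, 15.999),
            "HO": AtomType(LJParameters(1.0, 0.0, "no-LJ"), 0.418, 1.008),
        },
        # our convention u=(k/2)(r-r0)^2; OPLS tabulates u=K(r-r0)^2 -> k=2K
        bond_terms={
            "CC": BondTerm(r0=1.529, k=2 * 268.0 * KCAL),
            "CH": BondTerm(r0=1.090, k=2 * 340.0 * KCAL),
            "CO": BondTerm(r0=1.410, k=2 * 320.0 * KCAL),
            "OHb": BondTerm(r0=0.945, k=2 * 553.0 * KCAL),
        },
        angle_terms={
            "CCH": AngleTerm(theta0=110.7, k=2 * 37.5 * KCAL),
            "HCH": AngleTerm(theta0=107.8, k=2 * 33.0 * KCAL),
            "CCO": AngleTerm(theta0=108.0, k=2 * 50.0 * KCAL),
            "HCO": AngleTerm(theta0=109.5, k=2 * 35.0 * KCAL),
            "COH": AngleTerm(theta0=108.5, k=2 * 55.0 * KCAL),
        },
        # our c_n = V_n/2
        dihedral_terms={
            "HCCH": DihedralTerm(c3=0.318 / 2 * KCAL),
            "HCCO": DihedralTerm(c3=0.468 / 2 * KCAL),
            "HCOH": DihedralTerm(c3=0.352 / 2 * KCAL),
            "CCOH": DihedralTerm(c1=-0.356 / 2 * KCAL, c2=-0.174 / 2 * KCAL,
                                 c3=0.492 / 2 * KCAL),
        },
        exclusion_policy={2: (0.0, 0.0), 3: (0.0, 0.0), 4: (0.5, 0.5)},
        mixing_rule="geometric",
        r_cut=10.0,
        lrc_mode="tail",
        provenance="10.1021/ja9621760; energies kcal/mol (thermochemical calorie), "
                   "1-4 LJ and Coulomb scaled by 0.5",
    )
    return {"TraPPE-UA": trappe, "SPC/E": spce, "OPLS-AA-ethanol": opls}


# ---------------------------------------------------------------------------
# built-in molecule templates
# ---------------------------------------------------------------------------

def _methane() -> MoleculeTemplate:
    return MoleculeTemplate(
        name="methane-TraPPE", ff_name="TraPPE-UA", site_types=["CH4"],
        rigidity="point", reference_coords=np.zeros((1, 3)), rough_density=375.0,
    )


def _pentane() -> MoleculeTemplate:
    # all-trans backbone
    ref = _build_zmat([
        (0, 1.54, -1, 0, -1, 0),
        (1, 1.54, 0, 114.0, -1, 0),
        (2, 1.54, 1, 114.0, 0, 180.0),
        (3, 1.54, 2, 114.0, 1, 180.0),
    ])
    return MoleculeTemplate(
        name="pentane-TraPPE", ff_name="TraPPE-UA",
        site_types=["CH3", "CH2", "CH2", "CH2", "CH3"],
        bonds=[(0, 1, "CC"), (1, 2, "CC"), (2, 3, "CC"), (3, 4, "CC")],
        angles=[(0, 1, 2, "CCC"), (1, 2, 3, "CCC"), (2, 3, 4, "CCC")],
        dihedrals=[(0, 1, 2, 3, "CCCC"), (1, 2, 3, 4, "CCCC")],
        rigidity="fixed_bonds", reference_coords=ref, rough_density=560.0,
    )


def _benzene() -> MoleculeTemplate:
    # planar hexagon, C-C 1.40 Å -> circumradius 1.40 Å
    ang = np.arange(6) * math.pi / 3.0
    ref = np.column_stack([1.40 * np.cos(ang), 1.40 * np.sin(ang), np.zeros(6)])
    ref -= ref.mean(axis=0)
    bonds = [(i, (i + 1) % 6, "CCar") for i in range(6)]
    return MoleculeTemplate(
        name="benzene-TraPPE", ff_name="TraPPE-UA", site_types=["CHar"] * 6,
        bonds=bonds, rigidity="fully_rigid", reference_coords=ref,
        rough_density=750.0,
    )


def _water() -> MoleculeTemplate:
    half = math.radians(109.47 / 2.0)
    ref = np.array([
        [0.0, 0.0, 0.0],
        [math.cos(half), math.sin(half), 0.0],
        [math.cos(half), -math.sin(half), 0.0],
    ])
    ref -= ref.mean(axis=0)
    return MoleculeTemplate(
        name="water-SPC/E", ff_name="SPC/E", site_types=["OW", "HW", "HW"],
        bonds=[(0, 1, "OH"), (0, 2, "OH")],
        angles=[(1, 0, 2, "HOH")],
        rigidity="fully_rigid", reference_coords=ref, rough_density=1000.0,
    )


def _ethanol() -> MoleculeTemplate:
    # site order: C1(methyl C), C2(methylene C), O, HO, H11, H12, H13, H21, H22
    ref = _build_zmat([
        (0, 1.529, -1, 0, -1, 0),          # C2 from C1
        (1, 1.410, 0, 108.0, -1, 0),       # O from C2
        (2, 0.945, 1, 108.5, 0, 180.0),    # HO from O, anti to C1
        (0, 1.090, 1, 110.7, 2, 180.0),    # H11 from C1, anti to O
        (0, 1.090, 1, 110.7, 2, 60.0),     # H12
        (0, 1.090, 1, 110.7, 2, -60.0),    # H13
        (1, 1.090, 0, 110.7, 2, 120.0),    # H21 from C2
        (1, 1.090, 0, 110.7, 2, -120.0),   # H22
    ])
    bonds = [(0, 1, "CC"), (1, 2, "CO"), (2, 3, "OHb"),
             (0, 4, "CH"), (0, 5, "CH"), (0, 6, "CH"),
             (1, 7, "CH"), (1, 8, "CH")]
    angles = [
        (0, 1, 2, "CCO"), (1, 2, 3, "COH"),
        (4, 0, 1, "CCH"), (5, 0, 1, "CCH"), (6, 0, 1, "CCH"),
        (4, 0, 5, "HCH"), (4, 0, 6, "HCH"), (5, 0, 6, "HCH"),
        (7, 1, 0, "CCH"), (8, 1, 0, "CCH"),
        (7, 1, 2, "HCO"), (8, 1, 2, "HCO"),
        (7, 1, 8, "HCH"),
    ]
    dihedrals = [
        (0, 1, 2, 3, "CCOH"),
        (4, 0, 1, 2, "HCCO"), (5, 0, 1, 2, "HCCO"), (6, 0, 1, 2, "HCCO"),
        (4, 0, 1, 7, "HCCH"), (4, 0, 1, 8, "HCCH"),
        (5, 0, 1, 7, "HCCH"), (5, 0, 1, 8, "HCCH"),
        (6, 0, 1, 7, "HCCH"), (6, 0, 1, 8, "HCCH"),
        (7, 1, 2, 3, "HCOH"), (8, 1, 2, 3, "HCOH"),
    ]
    return MoleculeTemplate(
        name="ethanol-OPLS", ff_name="OPLS-AA-ethanol",
        site_types=["CT3", "CT2", "OH", "HO", "HC", "HC", "HC", "HC", "HC"],
        bonds=bonds, angles=angles, dihedrals=dihedrals,
        rigidity="fixed_bonds",    # MC default; flexible is a runtime switch
        reference_coords=ref, rough_density=800.0,
    )


_SHIPPED_FF_FILES = {
    "TraPPE-UA": "trappe_ua.json",
    "SPC/E": "spce.json",
    "OPLS-AA-ethanol": "opls_aa_ethanol.json",
}


def load_shipped_forcefield(name: str) -> ForceField:
    """Read one of the parameter files shipped with the package (the
    auditable on-disk form of :func:`builtin_forcefields`)."""
    from pathlib import Path

    from .ffparams import read_forcefield

    path = Path(__file__).parent / "data" / _SHIPPED_FF_FILES[name]
    return read_forcefield(path)


def builtin_models() -> dict[str, MoleculeTemplate]:
    """The five benchmark molecular models, keyed by name."""
    models = [_methane(), _pentane(), _benzene(), _water(), _ethanol()]
    return {m.name: m for m in models}


def builtin_state_points() -> list[StatePoint]:
    """The nine study state points."""
    rows = [
        StatePoint("methane-TraPPE", 900, 140.0, 1318.0, 14.0),
        StatePoint("pentane-TraPPE", 300, 372.0, 1402.0, 14.0),
        StatePoint("benzene-TraPPE", 400, 450.0, 2260.0, 14.0),
    ]
    for T in (280.0, 300.0, 320.0):
        rows.append(StatePoint("water-SPC/E", 1100, T, 101.325, 9.0))
    for T in (280.0, 300.0, 320.0):
        rows.append(StatePoint("ethanol-OPLS", 500, T, 101.325, 10.0))
    return rows


def estimated_box_edge(sp: StatePoint, density: float | None = None) -> float:
    """Equilibrium box edge (Å) estimated from a rough liquid density."""
    tmpl = builtin_models()[sp.model]
    ff = builtin_forcefields()[tmpl.ff_name]
    rho = density if density is not None else tmpl.rough_density
    volume = DENSITY_FACTOR * sp.N * tmpl.molar_mass(ff) / rho
    return volume ** (1.0 / 3.0)


def scaled_state_point(sp: StatePoint, N_new: int,
                       density: float | None = None) -> StatePoint:
    """Same intensive conditions with a reduced molecule count.

    Refuses when the estimated equilibrium box edge would drop below twice the
    cutoff; the error names the minimal admissible N.
    """
    if N_new < 2:
        raise ValueError("N_new must be >= 2")
    candidate = dc_replace(sp, N=N_new)
    edge = estimated_box_edge(candidate, density)
    if edge <= 2.0 * sp.r_cut:
        tmpl = builtin_models()[sp.model]
        ff = builtin_forcefields()[tmpl.ff_name]
        rho = density if density is not None else tmpl.rough_density
        n_min = math.ceil(
            (2.0 * sp.r_cut) ** 3 * rho / (DENSITY_FACTOR * tmpl.molar_mass(ff))
        ) + 1
        raise ValueError(
            f"box edge {edge:.1f} Å would not exceed 2*r_cut = {2 * sp.r_cut:.1f} Å; "
            f"minimal admissible N is {n_min}"
        )
    return candidate
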