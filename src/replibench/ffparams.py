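"""Force-field parameters, unit conversions, and parameter-provenance auditing.

The scientific background: Lennard-Jones well depths are published in several
unit systems (K via epsilon/k_B, kJ/mol, kcal/mol) and several functional forms
(the Berendsen A/B form for SPC/E water), and every published redistribution of
a force field has re-done these conversions with its own rounding and its own
values of the physical constants.  This module makes each conversion explicit
and exactly reproducible, and provides an audit that reports, digit by digit,
where two parameter sets stop agreeing.
"""

from __future__ import annotations

import decimal
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .constants import CONSTANTS, R_KJ

__all__ = [
    "LJParameters",
    "BerendsenAB",
    "AtomType",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "ForceField",
    "epsilon_to_kelvin",
    "kelvin_to_epsilon",
    "spce_from_AB",
    "ab_from_lj",
    "audit_parameter_sources",
    "round_trip_unit_error",
    "read_forcefield",
    "write_forcefield",
]


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def epsilon_to_kelvin(eps_kj: float) -> float:
    """Convert an LJ well depth from kJ/mol to its thermal equivalent in K.

    eps/k_B = eps_kj / (k_B N_A / 1000), evaluated in full double precision
    with the frozen 2019 SI constants.
    """
    if eps_kj < 0:
        raise ValueError(f"negative well depth: {eps_kj}")
    return eps_kj / R_KJ


def kelvin_to_epsilon(eps_kelvin: float) -> float:
    """Inverse of :func:`epsilon_to_kelvin` (K -> kJ/mol)."""
    if eps_kelvin < 0:
        raise ValueError(f"negative well depth: {eps_kelvin}")
    return eps_kelvin * R_KJ


@dataclass(frozen=True)
class BerendsenAB:
    """SPC/E LJ parameters in the original A/B form.

    u(r) = (B/r)^12 - (A/r)^6 with A in (kJ/mol)^(1/6) nm and
    B in (kJ/mol)^(1/12) nm.
    """

    A: float
    B: float

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must both be positive")


@dataclass(frozen=True)
class LJParameters:
    """sigma (Å) / epsilon (kJ/mol) pair with provenance metadata."""

    sigma: float
    epsilon: float
    source_label: str = ""
    stated_digits: dict | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


def spce_from_AB(ab: BerendsenAB, source_label: str = "") -> LJParameters:
    """Convert the Berendsen A/B form to sigma/epsilon.

    From 4 eps sigma^6 = A^6 and 4 eps sigma^12 = B^12:
    sigma = B^2/A (nm, returned in Å), eps = A^12/(4 B^12) (kJ/mol).
    No intermediate rounding is performed.
    """
    if ab.A == 0:
        raise ZeroDivisionError("A must be nonzero")
    sigma_nm = ab.B * ab.B / ab.A
    eps = ab.A**12 / (4.0 * ab.B**12)
    return LJParameters(sigma=sigma_nm * 10.0, epsilon=eps, source_label=source_label)


def ab_from_lj(lj: LJParameters) -> BerendsenAB:
    """Rebuild A = (4 eps sigma^6)^(1/6), B = (4 eps sigma^12)^(1/12) in nm units."""
    sigma_nm = lj.sigma / 10.0
    a = (4.0 * lj.epsilon) ** (1.0 / 6.0) * sigma_nm
    b = (4.0 * lj.epsilon) ** (1.0 / 12.0) * sigma_nm
    return BerendsenAB(A=a, B=b)


def _last_agreeing_decimal(x: float, y: float, max_digits: int = 20) -> int:
    """Last decimal place (1-based, digits after the point) at which the decimal
    expansions of x and y agree, comparing rounded representations.

    Returns -1 if they already disagree in the integer part, otherwise the
    count of agreeing decimal places (up to ``max_digits``).
    """
    if math.floor(x) != math.floor(y) and round(x) != round(y):
        return -1
    agree = 0
    for d in range(1, max_digits + 1):
        q = decimal.Decimal(1).scaleb(-d)
        dx = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_EVEN)
        dy = decimal.Decimal(repr(y)).quantize(q, rounding=decimal.ROUND_HALF_EVEN)
        if dx == dy:
            agree = d
        else:
            break
    return agree


def _stated_decimals(lj: LJParameters, field: str) -> int:
    """Decimal places a source actually states for a field: an explicit
    ``stated_digits`` entry if present, otherwise inferred from the shortest
    decimal representation of the value."""
    if lj.stated_digits and field in lj.stated_digits:
        return int(lj.stated_digits[field])
    text = repr(float(getattr(lj, field)))
    if "e" in text or "." not in text:
        return 17
    return len(text.split(".")[1])


def audit_parameter_sources(sets: list[LJParameters]):
    """Pairwise provenance audit of published LJ parameter sets.

    For every (ordered by input position) pair of parameter sets, report per
    field the last agreeing decimal place — capped at the stated precision of
    the less precise source, since agreement beyond a source's stated digits
    is unknowable — and the relative deviation of the second with respect to
    the first.  The report is symmetric in magnitude and reflexively zero.

    Returns a pandas DataFrame with columns
    ``(set_a, set_b, field, last_agreeing_decimal, relative_deviation)``.
    """
    import pandas as pd

    if len(sets) < 2:
        raise ValueError("need at least two parameter sets to audit")
    rows = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            for fname in ("sigma", "epsilon"):
                va, vb = getattr(a, fname), getattr(b, fname)
                rel = (vb - va) / va if va != 0 else math.inf
                cap = min(_stated_decimals(a, fname), _stated_decimals(b, fname))
                agree = min(_last_agreeing_decimal(va, vb), cap)
                rows.append(
                    {
                        "set_a": a.source_label or f"set{i}",
                        "set_b": b.source_label or f"set{j}",
                        "field": fname,
                        "last_agreeing_decimal": agree,
                        "relative_deviation": rel,
                    }
                )
    return pd.DataFrame(rows)


_ROUNDING = {
    "half-even": decimal.ROUND_HALF_EVEN,
    "half-up": decimal.ROUND_HALF_UP,
}


def round_trip_unit_error(
    eps_kelvin: float,
    decimals: int | None,
    unit: str = "kcal/mol",
    rounding: str = "half-even",
) -> float:
    """Emulate a limited-precision unit round trip of an LJ well depth.

    Converts eps/k_B (K) to ``unit``, rounds to ``decimals`` decimal places
    with the given rounding mode, and converts back to K.  The returned value
    quantifies the error introduced by an engine that stores the parameter in
    its native unit with finite precision.  ``decimals=None`` performs no
    rounding (identity up to conversion round-off).
    """
    if unit == "kcal/mol":
        factor = R_KJ / CONSTANTS.calorie
    elif unit == "kJ/mol":
        factor = R_KJ
    else:
        raise ValueError(f"unsupported unit: {unit!r}")
    value = eps_kelvin * factor
    if decimals is not None:
        if decimals < 0:
            raise ValueError("decimals must be >= 0")
        q = decimal.Decimal(1).scaleb(-decimals)
        value = float(
            decimal.Decimal(repr(value)).quantize(q, rounding=_ROUNDING[rounding])
        )
    return value / factor


# ---------------------------------------------------------------------------
# force-field container
# ---------------------------------------------------------------------------

@dataclass
class AtomType:
    lj: LJParameters
    charge: float        # e
    mass: float          # g/mol

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be strictly positive")


@dataclass
class BondTerm:
    """Fixed-length bond (k is None) or harmonic bond u = (k/2)(r-r0)^2.

    k in kJ/mol/Å^2; r0 in Å.  The (k/2) convention is stated here once and
    used everywhere; parameter files record it explicitly.
    """

    r0: float
    k: float | None = None

    @property
    def fixed(self) -> bool:
        return self.k is None


@dataclass
class AngleTerm:
    """Harmonic angle u = (k/2)(theta-theta0)^2, k in kJ/mol/rad^2, theta0 in deg."""

    theta0: float
    k: float | None = None   # None -> fixed by rigid geometry

    @property
    def theta0_rad(self) -> float:
        return math.radians(self.theta0)


@dataclass
class DihedralTerm:
    """Cosine series u = c0 + c1(1+cos phi) + c2(1-cos 2phi) + c3(1+cos 3phi).

    Coefficients in kJ/mol (the OPLS/TraPPE convention).
    """

    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0

    def energy(self, phi):
        import numpy as np

        return (
            self.c0
            + self.c1 * (1.0 + np.cos(phi))
            + self.c2 * (1.0 - np.cos(2.0 * phi))
            + self.c3 * (1.0 + np.cos(3.0 * phi))
        )


LRC_MODES = ("hard", "shifted", "tail")
MIXING_RULES = ("lorentz", "geometric")


@dataclass
class ForceField:
    """Typed force-field parameter collection with unit metadata and provenance.

    ``exclusion_policy`` maps bond-graph separation (1-2 -> 2, 1-3 -> 3, ...)
    to ``(lj_scale, coulomb_scale)``; separations beyond the largest key are
    included unscaled.
    """

    name: str
    atom_types: dict[str, AtomType]
    bond_terms: dict[str, BondTerm] = field(default_factory=dict)
    angle_terms: dict[str, AngleTerm] = field(default_factory=dict)
    dihedral_terms: dict[str, DihedralTerm] = field(default_factory=dict)
    exclusion_policy: dict[int, tuple[float, float]] = field(default_factory=dict)
    mixing_rule: str = "lorentz"
    pair_overrides: dict[tuple[str, str], LJParameters] = field(default_factory=dict)
    r_cut: float = 14.0
    lrc_mode: str = "tail"
    provenance: str = ""

    def __post_init__(self):
        if self.lrc_mode not in LRC_MODES:
            raise ValueError(f"lrc_mode must be one of {LRC_MODES}")
        if self.mixing_rule not in MIXING_RULES:
            raise ValueError(f"mixing_rule must be one of {MIXING_RULES}")

    def pair_params(self, type_a: str, type_b: str) -> tuple[float, float]:
        """Resolve (sigma, epsilon) for a type pair via override or mixing rule."""
        key = (type_a, type_b) if type_a <= type_b else (type_b, type_a)
        if key in self.pair_overrides:
            lj = self.pair_overrides[key]
            return lj.sigma, lj.epsilon
        a = self.atom_types[type_a].lj
        b = self.atom_types[type_b].lj
        if self.mixing_rule == "lorentz":
            sigma = 0.5 * (a.sigma + b.sigma)
        else:
            sigma = math.sqrt(a.sigma * b.sigma)
        eps = math.sqrt(a.epsilon * b.epsilon)
        return sigma, eps

    def nonbonded_scales(self, separation: int) -> tuple[float, float]:
        """(lj_scale, coulomb_scale) for an intramolecular pair at a given
        bond-graph separation (2 = 1-2 bonded neighbors)."""
        return self.exclusion_policy.get(separation, (1.0, 1.0))

    def replace(self, **kwargs) -> "ForceField":
        """Copy with selected fields replaced (r_cut, lrc_mode, ...)."""
        import copy

        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            if not hasattr(new, k):
                raise AttributeError(k)
            setattr(new, k, v)
        new.__post_init__()
        return new


# ---------------------------------------------------------------------------
# structured-text (JSON) force-field files
# ---------------------------------------------------------------------------

_UNITS = {
    "sigma": "angstrom",
    "epsilon": "kJ/mol",
    "charge": "e",
    "mass": "g/mol",
    "bond_r0": "angstrom",
    "bond_k": "kJ/mol/angstrom^2 (u = k/2 (r-r0)^2)",
    "angle_theta0": "degree",
    "angle_k": "kJ/mol/rad^2 (u = k/2 (theta-theta0)^2)",
    "dihedral_c": "kJ/mol (u = c0 + c1(1+cos) + c2(1-cos2) + c3(1+cos3))",
    "r_cut": "angstrom",
}


def write_forcefield(ff: ForceField, path: str | Path) -> None:
    """Serialize a force field to a key/value JSON file with unit tags.

    Floats are written with full ``repr`` precision so the read/write pair
    round-trips losslessly.
    """
    doc = {
        "format": "replibench-forcefield-1",
        "name": ff.name,
        "units": _UNITS,
        "provenance": ff.provenance,
        "mixing_rule": ff.mixing_rule,
        "r_cut": ff.r_cut,
        "lrc_mode": ff.lrc_mode,
        "atom_types": {
            name: {
                "sigma": t.lj.sigma,
                "epsilon": t.lj.epsilon,
                "source_label": t.lj.source_label,
                "stated_digits": t.lj.stated_digits,
                "charge": t.charge,
                "mass": t.mass,
            }
            for name, t in ff.atom_types.items()
        },
        "bond_terms": {k: asdict(v) for k, v in ff.bond_terms.items()},
        "angle_terms": {k: asdict(v) for k, v in ff.angle_terms.items()},
        "dihedral_terms": {k: asdict(v) for k, v in ff.dihedral_terms.items()},
        "exclusion_policy": {str(k): list(v) for k, v in ff.exclusion_policy.items()},
        "pair_overrides": {
            f"{a}|{b}": {"sigma": lj.sigma, "epsilon": lj.epsilon}
            for (a, b), lj in ff.pair_overrides.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_forcefield(path: str | Path) -> ForceField:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "replibench-forcefield-1":
        raise ValueError(f"{path}: not a replibench force-field file")
    atom_types = {
        name: AtomType(
            lj=LJParameters(
                sigma=t["sigma"],
                epsilon=t["epsilon"],
                source_label=t.get("source_label", ""),
                stated_digits=t.get("stated_digits"),
            ),
            charge=t["charge"],
            mass=t["mass"],
        )
        for name, t in doc["atom_types"].items()
    }
    return ForceField(
        name=doc["name"],
        atom_types=atom_types,
        bond_terms={k: BondTerm(**v) for k, v in doc["bond_terms"].items()},
        angle_terms={k: AngleTerm(**v) for k, v in doc["angle_terms"].items()},
        dihedral_terms={k: DihedralTerm(**v) for k, v in doc["dihedral_terms"].items()},
        exclusion_policy={
            int(k): tuple(v) for k, v in doc["exclusion_policy"].items()
        },
        mixing_rule=doc["mixing_rule"],
        pair_overrides={
            tuple(k.split("|")): LJParameters(sigma=v["sigma"], epsilon=v["epsilon"])
            for k, v in doc["pair_overrides"].items()
        },
        r_cut=doc["r_cut"],
        lrc_mode=doc["lrc_mode"],
        provenance=doc.get("provenance", ""),
    )
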