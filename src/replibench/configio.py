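"""Initial configurations, exact constraints, and snapshot serialization.

The canonical snapshot format is structured text (JSON) with full-precision
decimal representations of every double, so that a write/read round trip is
bit-exact.  The PDB/GRO/XYZ dialects deliberately reproduce the fixed-width
column layouts of those formats, because the precision lost in those columns
is itself one of the initialization-error sources this package quantifies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ffparams import ForceField
from .models import MoleculeTemplate, StatePoint, builtin_models, builtin_forcefields

__all__ = [
    "Snapshot",
    "build_lattice_config",
    "project_constraints",
    "truncate_coordinates",
    "read_snapshot",
    "write_snapshot",
    "write_pdb", "read_pdb", "write_gro", "read_gro", "write_xyz", "read_xyz",
    "random_rotation_matrix",
]

DIALECTS = ("lossless", "pdb", "gro", "xyz18", "f32")


@dataclass
class Snapshot:
    """Periodic cubic box + per-site coordinates + molecule/site index maps.

    Sites of one molecule are contiguous and stored unwrapped (bonded
    geometry is unambiguous); the minimum image is applied at energy time.
    """

    box: float                      # cubic edge length, Å
    coords: np.ndarray              # (n_sites, 3), Å
    mol_index: np.ndarray           # site -> molecule id
    mol_templates: list[str]        # molecule -> template name
    velocities: np.ndarray | None = None   # (n_sites, 3), Å/ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if len(self.mol_index) != len(self.coords):
            raise ValueError("mol_index length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.coords)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_templates)

    def mol_slices(self) -> list[slice]:
        bounds = np.searchsorted(self.mol_index, np.arange(self.n_molecules + 1))
        return [slice(bounds[i], bounds[i + 1]) for i in range(self.n_molecules)]

    def copy(self) -> "Snapshot":
        return Snapshot(
            box=self.box,
            coords=self.coords.copy(),
            mol_index=self.mol_index.copy(),
            mol_templates=list(self.mol_templates),
            velocities=None if self.velocities is None else self.velocities.copy(),
        )


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake quaternion method)."""
    u1, u2, u3 = rng.random(3)
    q = np.array([
        math.sqrt(1 - u1) * math.sin(2 * math.pi * u2),
        math.sqrt(1 - u1) * math.cos(2 * math.pi * u2),
        math.sqrt(u1) * math.sin(2 * math.pi * u3),
        math.sqrt(u1) * math.cos(2 * math.pi * u3),
    ])
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def build_lattice_config(sp: StatePoint, seed: int,
                         density_guess: float | None = None) -> Snapshot:
    """Molecules on a cubic lattice with seeded uniform random orientations.

    The box is sized from ``density_guess`` (kg/m^3; default: the template's
    rough liquid density).  Deterministic for a given (state point, seed); the
    disordering of the lattice is the job of the high-temperature melt stage.
    """
    from .models import estimated_box_edge

    tmpl = builtin_models()[sp.model]
    L = estimated_box_edge(sp, density_guess)
    n_side = math.ceil(sp.N ** (1.0 / 3.0))
    if n_side**3 < sp.N:
        raise ValueError("lattice capacity below N")
    spacing = L / n_side
    rng = np.random.default_rng(seed)

    ref = tmpl.reference_coords
    coords = np.empty((sp.N * tmpl.n_sites, 3))
    mol_index = np.repeat(np.arange(sp.N), tmpl.n_sites)
    k = 0
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                if k >= sp.N:
                    break
                center = (np.array([ix, iy, iz]) + 0.5) * spacing
                if tmpl.n_sites == 1:
                    coords[k] = center
                else:
                    R = random_rotation_matrix(rng)
                    coords[k * tmpl.n_sites:(k + 1) * tmpl.n_sites] = ref @ R.T + center
                k += 1
    return Snapshot(box=L, coords=coords, mol_index=mol_index,
                    mol_templates=[tmpl.name] * sp.N)


# ---------------------------------------------------------------------------
# constraint projection
# ---------------------------------------------------------------------------

def _kabsch(ref: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Best-fit rigid transform of ``ref`` onto ``cur`` (both centered copies)."""
    rc = ref - ref.mean(axis=0)
    cc = cur - cur.mean(axis=0)
    H = rc.T @ cc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return rc @ R.T + cur.mean(axis=0)


def project_constraints(
    snap: Snapshot,
    templates: dict[str, MoleculeTemplate] | None = None,
    forcefields: dict[str, ForceField] | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> tuple[Snapshot, float]:
    """Restore exact fixed bond lengths (and rigid geometries).

    Fully rigid molecules are replaced by the best-fit (Kabsch) superposition
    of their reference geometry, which restores every internal distance at
    once.  Fixed-bond molecules are corrected iteratively, moving both bond
    endpoints by equal and opposite displacements (center of mass preserved),
    until the worst relative bond-length error is <= ``tol``.

    Returns the corrected snapshot and the achieved maximum relative error.
    """
    templates = templates or builtin_models()
    forcefields = forcefields or builtin_forcefields()
    out = snap.copy()
    worst = 0.0
    for mslice, tname in zip(out.mol_slices(), out.mol_templates):
        tmpl = templates[tname]
        ff = forcefields[tmpl.ff_name]
        if tmpl.rigidity in ("point", "flexible"):
            continue
        pos = out.coords[mslice]
        if tmpl.rigidity == "fully_rigid":
            out.coords[mslice] = _kabsch(tmpl.reference_coords, pos)
            err = _max_bond_error(out.coords[mslice], tmpl, ff)
            worst = max(worst, err)
            continue
        # fixed_bonds: every bond is constrained to its r0 (the rigidity flag
        # governs, even when the force field tabulates a harmonic constant)
        fixed = [(i, j, ff.bond_terms[key].r0) for i, j, key in tmpl.bonds]
        if not fixed:
            continue
        err = math.inf
        for _ in range(max_iter):
            err = 0.0
            for i, j, r0 in fixed:
                d = pos[j] - pos[i]
                r = np.linalg.norm(d)
                e = abs(r - r0) / r0
                err = max(err, e)
                corr = 0.5 * (r - r0) / r * d
                pos[i] += corr
                pos[j] -= corr
            if err <= tol:
                break
        else:
            ij = max(fixed, key=lambda b: abs(
                np.linalg.norm(pos[b[1]] - pos[b[0]]) - b[2]))
            raise RuntimeError(
                f"constraint projection did not converge for {tname}; "
                f"worst bond {ij[0]}-{ij[1]} (target {ij[2]} Å)"
            )
        out.coords[mslice] = pos
        worst = max(worst, err)
    return out, worst


def _max_bond_error(pos: np.ndarray, tmpl: MoleculeTemplate, ff: ForceField) -> float:
    err = 0.0
    for i, j, key in tmpl.bonds:
        r0 = ff.bond_terms[key].r0
        r = float(np.linalg.norm(pos[j] - pos[i]))
        err = max(err, abs(r - r0) / r0)
    return err


# ---------------------------------------------------------------------------
# precision dialects
# ---------------------------------------------------------------------------

def _roundtrip_fixed(x: np.ndarray, fmt: str, scale: float, width: int) -> np.ndarray:
    flat = x.ravel()
    out = np.empty_like(flat)
    for i, v in enumerate(flat):
        s = fmt % (v * scale)
        if len(s) > width:
            raise ValueError(
                f"coordinate {v} Å exceeds the {width}-character field of this dialect"
            )
        out[i] = float(s) / scale
    return out.reshape(x.shape)


def truncate_coordinates(snap: Snapshot, dialect: str) -> Snapshot:
    """Round-trip coordinates through a coordinate-file precision dialect.

    dialects: ``pdb`` (Å, 3 decimals, 8-char field), ``gro`` (nm, 3 decimals,
    8-char field), ``xyz18`` (Å, 18-char field, 12 decimals), ``f32`` (binary
    single precision), ``lossless`` (identity).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    out = snap.copy()
    if dialect == "lossless":
        return out
    if dialect == "f32":
        out.coords = out.coords.astype(np.float32).astype(np.float64)
        return out
    if dialect == "pdb":
        out.coords = _roundtrip_fixed(out.coords, "%8.3f", 1.0, 8)
    elif dialect == "gro":
        out.coords = _roundtrip_fixed(out.coords, "%8.3f", 0.1, 8)
    elif dialect == "xyz18":
        out.coords = _roundtrip_fixed(out.coords, "%18.12f", 1.0, 18)
    return out


# ---------------------------------------------------------------------------
# lossless structured-text snapshots
# ---------------------------------------------------------------------------

def write_snapshot(snap: Snapshot, path: str | Path) -> None:
    doc = {
        "format": "replibench-snapshot-1",
        "box": snap.box,
        "coordinates": snap.coords.tolist(),
        "molecule_index": snap.mol_index.tolist(),
        "template_index": snap.mol_templates,
    }
    if snap.velocities is not None:
        doc["velocities"] = snap.velocities.tolist()
    Path(path).write_text(json.dumps(doc))


def read_snapshot(path: str | Path) -> Snapshot:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: parse error at line {exc.lineno}") from exc
    if doc.get("format") != "replibench-snapshot-1":
        raise ValueError(f"{path}: not a replibench snapshot")
    return Snapshot(
        box=doc["box"],
        coords=np.array(doc["coordinates"], dtype=float),
        mol_index=np.array(doc["molecule_index"], dtype=int),
        mol_templates=list(doc["template_index"]),
        velocities=(np.array(doc["velocities"], dtype=float)
                    if "velocities" in doc else None),
    )


# ---------------------------------------------------------------------------
# coordinate-file dialects (standard column layouts)
# ---------------------------------------------------------------------------

def _site_names(snap: Snapshot) -> list[str]:
    models = builtin_models()
    names = []
    for sl, t in zip(snap.mol_slices(), snap.mol_templates):
        n = sl.stop - sl.start
        if t in models and models[t].n_sites == n:
            names.extend(models[t].site_types)
        else:
            names.extend(["X"] * n)
    return names


def write_pdb(snap: Snapshot, path: str | Path) -> None:
    """Standard PDB ATOM records: coordinates in Å, columns 31-54, %8.3f."""
    names = _site_names(snap)
    lines = [
        f"CRYST1{snap.box:9.3f}{snap.box:9.3f}{snap.box:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    ]
    for i, (xyz, m) in enumerate(zip(snap.coords, snap.mol_index)):
        name = names[i][:4] if i < len(names) else "X"
        resname = snap.mol_templates[m][:3].upper()
        lines.append(
            "ATOM  %5d %-4s %-3s  %4d    %8.3f%8.3f%8.3f  1.00  0.00"
            % ((i % 99999) + 1, name, resname, (m % 9999) + 1, *xyz)
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path, like: Snapshot | None = None) -> Snapshot:
    """Read ATOM records; molecule map from residue ids (or from ``like``)."""
    coords, resids = [], []
    box = None
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("CRYST1"):
            box = float(line[6:15])
        elif line.startswith(("ATOM", "HETATM")):
            try:
                coords.append([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])])
                resids.append(int(line[22:26]))
            except ValueError as exc:
                raise ValueError(f"{path}: parse error at line {ln}") from exc
    if box is None or not coords:
        raise ValueError(f"{path}: missing CRYST1 or ATOM records")
    coords = np.array(coords)
    if like is not None:
        return Snapshot(box=box, coords=coords, mol_index=like.mol_index.copy(),
                        mol_templates=list(like.mol_templates))
    _, mol_index = np.unique(resids, return_inverse=True)
    return Snapshot(box=box, coords=coords, mol_index=mol_index,
                    mol_templates=["unknown"] * (mol_index.max() + 1))


def write_gro(snap: Snapshot, path: str | Path) -> None:
    """GRO 87 layout: positions in nm %8.3f, velocities in nm/ps %8.4f."""
    names = _site_names(snap)
    lines = ["replibench snapshot", f"{snap.n_sites:5d}"]
    for i, (xyz, m) in enumerate(zip(snap.coords, snap.mol_index)):
        resname = snap.mol_templates[m][:5]
        vel = ""
        if snap.velocities is not None:
            vel = "%8.4f%8.4f%8.4f" % tuple(snap.velocities[i] / 10.0)
        lines.append(
            "%5d%-5s%5s%5d%8.3f%8.3f%8.3f%s"
            % ((m % 99999) + 1, resname, names[i][:5], (i % 99999) + 1,
               *(snap.coords[i] / 10.0), vel)
        )
    b = snap.box / 10.0
    lines.append("%10.5f%10.5f%10.5f" % (b, b, b))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path: str | Path, like: Snapshot | None = None) -> Snapshot:
    text = Path(path).read_text().splitlines()
    try:
        n = int(text[1])
        coords = np.empty((n, 3))
        vels = np.zeros((n, 3))
        has_vel = False
        resids = []
        for i in range(n):
            line = text[2 + i]
            resids.append(int(line[0:5]))
            coords[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line.rstrip()) > 44:
                vels[i] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                has_vel = True
        box = float(text[2 + n].split()[0]) * 10.0
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed GRO file") from exc
    coords *= 10.0     # nm -> Å
    vels *= 10.0       # nm/ps -> Å/ps
    if like is not None:
        return Snapshot(box=box, coords=coords, mol_index=like.mol_index.copy(),
                        mol_templates=list(like.mol_templates),
                        velocities=vels if has_vel else None)
    _, mol_index = np.unique(resids, return_inverse=True)
    return Snapshot(box=box, coords=coords, mol_index=mol_index,
                    mol_templates=["unknown"] * (mol_index.max() + 1),
                    velocities=vels if has_vel else None)


def write_xyz(snap: Snapshot, path: str | Path, width: int = 18) -> None:
    """XYZ with 18-character coordinate fields (Å)."""
    names = _site_names(snap)
    fmt = f"%{width}.{width - 6}f"
    lines = [str(snap.n_sites), f"box {snap.box!r}"]
    for i, xyz in enumerate(snap.coords):
        lines.append(("%-4s " % names[i][:4]) + " ".join(fmt % c for c in xyz))
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, like: Snapshot | None = None) -> Snapshot:
    text = Path(path).read_text().splitlines()
    try:
        n = int(text[0])
        box = float(text[1].split()[1])
        coords = np.array([[float(v) for v in text[2 + i].split()[1:4]]
                           for i in range(n)])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed XYZ file") from exc
    if like is not None:
        return Snapshot(box=box, coords=coords, mol_index=like.mol_index.copy(),
                        mol_templates=list(like.mol_templates))
    return Snapshot(box=box, coords=coords, mol_index=np.arange(n),
                    mol_templates=["unknown"] * n)
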