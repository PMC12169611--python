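"""Equilibration detection, replicate statistics, and structural analysis.

Replicate statistics follow the cross-engine comparison protocol: for each
engine configuration the production means of the independent replicas are
averaged to a sample mean with a Student-t 95% confidence interval, and
engine configurations are compared through the relative percentage deviation
delta = 100 (rho_engine - rho_all)/rho_all about the unweighted pooled mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ReplicateStats",
    "HBCriterion",
    "statistical_inefficiency",
    "detect_equilibration",
    "replicate_statistics",
    "error_groupings",
    "rdf_cdf",
    "count_hydrogen_bonds",
    "bond_length_distribution",
]


# ---------------------------------------------------------------------------
# equilibration detection
# ---------------------------------------------------------------------------

def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n]
    acf /= np.arange(n, 0, -1)       # unbiased-count normalization
    if acf[0] <= 0:
        return np.zeros(n)
    return acf / acf[0]


def statistical_inefficiency(x: np.ndarray, max_lag: int | None = None) -> float:
    """g = 1 + 2 sum_t (1 - t/n) C(t), truncated at the first non-positive
    autocorrelation (the positive-sequence estimator).  Constant series -> 1."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or np.var(x) == 0:
        return 1.0
    C = _autocorr_fft(x)
    tmax = min(n - 1, max_lag or n - 1)
    g = 1.0
    for t in range(1, tmax):
        if C[t] <= 0:
            break
        g += 2.0 * C[t] * (1.0 - t / n)
    return max(g, 1.0)


def detect_equilibration(series: np.ndarray, n_candidates: int = 100
                         ) -> tuple[int, float, float]:
    """Choose the production start maximizing the effective sample count.

    Scans candidate start indices, computes the statistical inefficiency g of
    each suffix and N_eff = (n - start)/g, and returns
    (start, g, N_eff) at the maximum.  A constant series returns (0, 1, n).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short (need >= 10 points)")
    if np.var(x) == 0:
        return 0, 1.0, float(n)
    starts = np.unique(np.linspace(0, n - 10, min(n_candidates, n - 10),
                                   dtype=int))
    best = (0, 1.0, -1.0)
    for s in starts:
        g = statistical_inefficiency(x[s:])
        neff = (n - s) / g
        if neff > best[2]:
            best = (int(s), g, neff)
    return best


def equilibration_passed(series: np.ndarray, min_uncorrelated: int = 100,
                         min_fraction: float = 0.8) -> bool:
    """The study's gate: at least 100 uncorrelated samples, or at least 80%
    of the series judged equilibrated."""
    start, _g, neff = detect_equilibration(series)
    return neff >= min_uncorrelated or (len(series) - start) / len(series) >= min_fraction


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

@dataclass
class ReplicateStats:
    """Grand mean over replicate production means with Student-t 95% CI."""

    replicate_means: np.ndarray
    mean: float
    ci95: float

    @property
    def n(self) -> int:
        return len(self.replicate_means)

    def delta_vs(self, pooled_mean: float) -> float:
        """Relative percentage deviation about an unweighted pooled mean."""
        return 100.0 * (self.mean - pooled_mean) / pooled_mean


def _production_mean(run) -> float:
    if getattr(run, "prod_acc_n", 0):
        return run.rho_mean
    return float(np.mean(run.rho_production()))


def replicate_statistics(runs: list, pooled_mean: float | None = None
                         ) -> ReplicateStats:
    """Per-replicate production means -> grand mean and t-based 95% CI
    (n-1 degrees of freedom)."""
    if len(runs) < 2:
        raise ValueError("need at least two replicates")
    means = np.array([_production_mean(r) for r in runs])
    m = float(means.mean())
    sd = float(means.std(ddof=1))
    tcrit = float(sps.t.ppf(0.975, len(means) - 1))
    ci = tcrit * sd / math.sqrt(len(means))
    return ReplicateStats(replicate_means=means, mean=m, ci95=ci)


def error_groupings(all_runs: list) -> dict[str, dict]:
    """Three deviation groupings of a replicate campaign (percent).

    Runs must carry ``label`` (engine configuration) and ``method``
    ('mc' or 'md').  Returns, each with 'deviations', 'min', 'max':

    - ``per_simulation_vs_pooled``: every run against the pooled mean;
    - ``per_simulation_vs_class``: every run against its MD/MC class mean;
    - ``per_configuration_vs_pooled``: each configuration's replicate mean
      against the pooled mean (the replicability view; spread shrinks roughly
      as 1/sqrt(n_replicates)).
    """
    rhos = np.array([_production_mean(r) for r in all_runs])
    labels = [r.label or r.method for r in all_runs]
    methods = [r.method for r in all_runs]
    pooled = rhos.mean()
    out = {}
    dev1 = 100.0 * (rhos - pooled) / pooled
    out["per_simulation_vs_pooled"] = dev1
    class_means = {m: rhos[[i for i, mm in enumerate(methods) if mm == m]].mean()
                   for m in set(methods)}
    dev2 = np.array([100.0 * (r - class_means[m]) / class_means[m]
                     for r, m in zip(rhos, methods)])
    out["per_simulation_vs_class"] = dev2
    config_means = {}
    for lab, r in zip(labels, rhos):
        config_means.setdefault(lab, []).append(r)
    dev3 = np.array([100.0 * (np.mean(v) - pooled) / pooled
                     for v in config_means.values()])
    out["per_configuration_vs_pooled"] = dev3
    return {k: {"deviations": v, "min": float(v.min()), "max": float(v.max())}
            for k, v in out.items()}


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------

def rdf_cdf(snapshots: list, pair_selection: tuple[str, str] | None = None,
            bin_width: float = 0.1, r_max: float | None = None,
            templates: dict | None = None):
    """Radial distribution function g(r) and running coordination number n(r).

    ``pair_selection`` names two site types (None: all sites).  Intramolecular
    pairs are excluded.  Normalization: ideal-gas shell counts, so g -> 1 for
    a uniform fluid; n(r) is the mean number of B neighbors of an A site.
    """
    from .models import builtin_models

    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    templates = templates or builtin_models()
    snaps = snapshots if isinstance(snapshots, list) else [snapshots]
    L = snaps[0].box
    rmax = r_max if r_max is not None else L / 2.0
    if rmax > L / 2.0 + 1e-9:
        raise ValueError("r range exceeds half the box")
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_a = n_b = 0
    for snap in snaps:
        types = []
        for t in snap.mol_templates:
            types.extend(templates[t].site_types)
        types = np.array(types)
        if pair_selection is None:
            ia = ib = np.arange(snap.n_sites)
        else:
            ia = np.nonzero(types == pair_selection[0])[0]
            ib = np.nonzero(types == pair_selection[1])[0]
        n_a, n_b = len(ia), len(ib)
        pos = snap.coords
        d = pos[ia][:, None, :] - pos[ib][None, :, :]
        d -= snap.box * np.round(d / snap.box)
        r = np.sqrt((d**2).sum(axis=-1))
        same_mol = snap.mol_index[ia][:, None] == snap.mol_index[ib][None, :]
        mask = ~same_mol
        hist += np.histogram(r[mask], bins=edges)[0]
    n_frames = len(snaps)
    V = snaps[0].box ** 3
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_a * (n_b / V) * shell * n_frames
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    n_r = np.cumsum(hist) / (n_frames * max(n_a, 1))
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    return r_mid, g, n_r


@dataclass(frozen=True)
class HBCriterion:
    """Elliptical hydrogen-bond criterion on (O-O distance, D-H-A angle).

    A pair is hydrogen bonded iff
    ((d - center_d)/width_d)^2 + ((theta - center_a)/width_a)^2 <= 1
    (inclusive boundary; angle in degrees, the donor-hydrogen-acceptor
    interior angle).
    """

    center_distance: float = 2.75   # Å
    center_angle: float = 180.0     # degrees
    width_distance: float = 0.5     # Å
    width_angle: float = 50.0       # degrees

    def is_bonded(self, d: float, theta_deg: float) -> bool:
        return (((d - self.center_distance) / self.width_distance) ** 2
                + ((theta_deg - self.center_angle) / self.width_angle) ** 2) <= 1.0


def count_hydrogen_bonds(snapshots: list, criterion: HBCriterion | None = None,
                         templates: dict | None = None) -> np.ndarray:
    """Number of hydrogen bonds per snapshot (whole system).

    Donors are O sites with a bonded H; acceptors are O sites on other
    molecules; each ordered donor->acceptor pair counts at most once per
    donor hydrogen.  Models without O and H sites are refused.
    """
    from .models import builtin_models

    criterion = criterion or HBCriterion()
    templates = templates or builtin_models()
    snaps = snapshots if isinstance(snapshots, list) else [snapshots]
    counts = []
    for snap in snaps:
        slices = snap.mol_slices()
        donors = []   # (O index global, H index global)
        acceptors = []  # O index global
        for sl, tname in zip(slices, snap.mol_templates):
            tmpl = templates[tname]
            o_local = [i for i, t in enumerate(tmpl.site_types)
                       if t.upper().startswith("O")]
            if not o_local:
                continue
            for o in o_local:
                acceptors.append(sl.start + o)
                for i, j, _k in tmpl.bonds:
                    if i == o and tmpl.site_types[j].upper().startswith("H"):
                        donors.append((sl.start + o, sl.start + j))
                    elif j == o and tmpl.site_types[i].upper().startswith("H"):
                        donors.append((sl.start + o, sl.start + i))
        if not donors or not acceptors:
            raise ValueError("model exposes no O-H donor/acceptor sites")
        L = snap.box
        n_hb = 0
        pos = snap.coords
        acc = np.array(acceptors)
        for o_d, h_d in donors:
            d_oo = pos[acc] - pos[o_d]
            d_oo -= L * np.round(d_oo / L)
            dist = np.sqrt((d_oo**2).sum(axis=1))
            for k, o_a in enumerate(acc):
                if snap.mol_index[o_a] == snap.mol_index[o_d]:
                    continue
                if dist[k] > criterion.center_distance + criterion.width_distance:
                    continue
                # donor-H-acceptor interior angle at the hydrogen
                v1 = pos[o_d] - pos[h_d]
                v2 = pos[o_a] - pos[h_d]
                v2 -= L * np.round(v2 / L)
                cosang = float(np.dot(v1, v2)
                               / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if criterion.is_bonded(dist[k], theta):
                    n_hb += 1
        counts.append(n_hb)
    return np.array(counts)


def bond_length_distribution(snapshots: list, bond_key: str,
                             templates: dict | None = None,
                             bins: int = 60):
    """Histogram and mean of the lengths of all bonds carrying ``bond_key``.

    For fixed-bond trajectories this is a delta at the constraint value.
    Returns (bin_centers, counts, mean).
    """
    from .models import builtin_models

    templates = templates or builtin_models()
    snaps = snapshots if isinstance(snapshots, list) else [snapshots]
    lengths = []
    for snap in snaps:
        for sl, tname in zip(snap.mol_slices(), snap.mol_templates):
            tmpl = templates[tname]
            p = snap.coords[sl]
            for i, j, key in tmpl.bonds:
                if key == bond_key:
                    lengths.append(float(np.linalg.norm(p[j] - p[i])))
    if not lengths:
        raise ValueError(f"no bonds with key {bond_key!r} in these snapshots")
    lengths = np.array(lengths)
    span = lengths.max() - lengths.min()
    if span < 1e-9:
        # fixed-bond trajectory: a delta needs an explicit window
        rng_ = (lengths[0] - 0.05, lengths[0] + 0.05)
        counts, edges = np.histogram(lengths, bins=bins, range=rng_)
    else:
        counts, edges = np.histogram(lengths, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, float(lengths.mean())
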