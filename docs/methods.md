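# Methods

`replibench` implements, in one self-contained package, the computational
chain needed to ask "do two implementations of the same molecular model give
the same liquid density?" — exact force-field unit handling, decomposed
single-point energies, staged NpT Metropolis Monte Carlo, a deliberately
minimal LJ/WCA molecular-dynamics engine, and the replicate statistics used
to compare engine configurations.  This note records the models, the
conventions, and the design choices that were genuinely open.

## Models and parameters

Five benchmark models of increasing complexity are built in:

| model | sites | rigidity | force field | electrostatics |
|---|---|---|---|---|
| methane (united atom) | 1 | point | TraPPE-UA | none |
| n-pentane (united atom) | 5 | fixed bonds | TraPPE-UA | none |
| benzene (united atom) | 6 | fully rigid | TraPPE-UA | none |
| water | 3 | fully rigid | SPC/E | Ewald |
| ethanol (all atom) | 9 | fixed bonds (switchable) | OPLS-AA | Ewald |

Internal units are kJ/mol, Å, K, kPa, g/mol and ps throughout; every
conversion goes through the frozen 2019 SI constants
(k_B = 1.380649e-23 J/K, N_A = 6.02214076e23 /mol, thermochemical calorie
4.184 J).  TraPPE well depths are published as eps/k_B in K and converted at
full double precision; OPLS parameters are published in kcal/mol; the SPC/E
oxygen LJ parameters are derived from Berendsen's original A/B constants
(A = 0.37122 (kJ/mol)^(1/6) nm, B = 0.3428 (kJ/mol)^(1/12) nm) via
sigma = B^2/A and eps = A^12/(4 B^12) with no intermediate rounding.  The
epsilon ordering A^12/(4 B^12) is chosen because it reproduces the published
high-precision thermal value bit-for-bit when divided by k_B N_A; other
algebraically equivalent orderings differ by 1 ulp.

Site masses are composed from IUPAC standard atomic weights
(CH4 16.043, CH3 15.035, CH2 14.027, aromatic CH 13.019, C 12.011,
O 15.999, H 1.008 g/mol) and are stored in the force-field files so they are
auditable.  Mixing rules: Lorentz–Berthelot (arithmetic sigma, geometric
epsilon) for TraPPE-UA, geometric for both in OPLS-AA.  Exclusions: TraPPE
excludes LJ and Coulomb entirely for 1-2/1-3/1-4 neighbors and includes 1-5
and beyond unscaled; OPLS-AA scales 1-4 LJ and Coulomb by 0.5.  Harmonic
terms use the u = (k/2)(x - x0)^2 convention everywhere; the shipped
parameter files state this explicitly, and OPLS constants (tabulated under
the K(x - x0)^2 convention) are doubled on entry.

The ethanol reference geometry places hydrogens at ideal staggered
positions; the OPLS equilibrium angles at a tetrahedral carbon are mutually
incompatible, so the reference geometry carries a small (~0.03 kJ/mol per
molecule) residual angle energy rather than exactly zero — this is a
property of the force field, not an error.

## Single-point energies

The energy report decomposes into LJ pair, LJ tail, Ewald real/reciprocal/
self/exclusion, bond, angle, dihedral, and intramolecular nonbonded parts;
the total is their `fsum` and is checked to 1e-10 relative in tests.  All
pair sums run in a fixed order (sorted site-index pairs, chunked rows), so a
snapshot always yields a bit-identical report.

Cutoff treatments: `hard` truncates the pair potential at r_cut; `shifted`
additionally subtracts the pair value at r_cut inside the cutoff (leaving
forces unchanged); `tail` adds the standard analytic energy and pressure
corrections assuming unit pair correlation beyond the cutoff, with all type
pairs counted N_a N_b (the uniform-fluid convention; intramolecular
exclusions are not depleted from the tail, matching common engine practice).
A hard inner cutoff of 1 Å returns an infinite-energy sentinel that the MC
samplers consume as automatic rejection.

Ewald summation uses tinfoil boundaries, erfc-screened real space truncated
at r_cut (intermolecular pairs only), a reciprocal sum over integer vectors
with |n| <= kmax, the standard self term, and a per-molecule correction that
subtracts the erf-screened interaction for every intramolecular pair at its
true (bonded, not minimum-image) separation — molecules here are far smaller
than the box, where the two conventions agree.  Defaults follow the study
settings kappa = 3.6/r_cut and kmax = int(kappa L) + 1; an accuracy-targeted
mode raises kmax until the reciprocal sum is converged to a relative target
(default 1e-10).  Two accuracy caveats discovered while testing: the
kappa = 3.6/r_cut setting leaves a real-space truncation of order
erfc(3.6) ~ 4e-7, so total-energy invariance under kappa variation at the
1e-8 level only holds for kappa r_cut >= ~4.8; and rotating a periodic
configuration genuinely changes the electrostatic energy through the image
lattice (~1e-4..1e-3 relative for small clusters), so exact rotation
invariance is only asserted for the short-ranged terms.

The virial pressure uses the molecular convention
P = (N_mol k_B T + W/3)/V + p_tail with W summed over intermolecular LJ
pairs; the reciprocal-space Coulomb virial is not implemented (the MC
barostat never needs it — volume moves use the external pressure — so the
field is reporting-only and is exact for the uncharged models).

## Configurations, constraints, and precision dialects

Initial configurations place molecular centers on a cubic lattice sized from
a rough liquid density, with orientations drawn uniformly (Shoemake
quaternions) from a seeded generator; the high-temperature melt stage is
responsible for disordering them.  This replaces random packing as the
canonical initializer precisely because seeded lattices are bit-reproducible
across platforms.

Constraint projection restores exact fixed geometry: fully rigid molecules
are replaced by the Kabsch best-fit superposition of their reference
geometry; fixed-bond molecules are corrected by iterative symmetric bond
projections (center of mass preserved) until the worst relative bond error
is <= 1e-7, the tolerance used for validating initial structures.

The snapshot format is JSON with full-`repr` doubles (bit-exact round
trips).  The PDB (Å, three decimals), GRO (nm, three decimals), 18-character
XYZ, and binary-float32 dialects emulate the coordinate precision of real
engine input files; `truncate_coordinates` writes and re-reads coordinates
through the corresponding fixed-width formatter, and the induced
single-point energy shift is verified to rank lossless <= xyz18 <= f32 <=
gro/pdb.

## NpT Monte Carlo

One MC cycle (MCC) is N attempted moves.  Volume moves are selected with
probability 0.01 (2.5/N for the charged systems, giving roughly one accepted
volume move per cycle); the remainder splits equally over molecular
translations, rigid rotations (absent for methane) and CBMC regrowth
(pentane/ethanol only).  Volume moves are proposed uniformly in ln V and
accepted with min[1, exp(-beta dU - beta p dV + (N+1) ln(V'/V))]; the ln V
convention is chosen for scale invariance and the ideal-gas closed form
<V> = (N+1) k_B T/p under this convention is a test oracle.  Rotations use a
uniformly random axis by default, with the single-Cartesian-axis variant
available as a schedule switch.  During equilibration stages the maximum
displacements adapt multiplicatively toward a 40% acceptance target
(clamped: d_trans <= L/4, d_rot <= pi, d_lnV <= 0.5) and are frozen for
production.  Number and specific densities are accumulated after every
attempted move, so every configuration carries equal weight.

The staged workflow is: NVT melt at 1000 K, NVT cool at the target
temperature, up to three NpT equilibration blocks gated by the
statistical-inefficiency test (pass when at least 100 uncorrelated samples
or 80% of the block is judged equilibrated), then a production NpT stage.
The full-scale preset uses 5000/5000/40000x3/120000 MCC with samples every
10 MCC; the desk preset (500/500/4000/16000) exists for reduced-N replicate
campaigns on a single CPU, and the test suite uses smaller stages still —
scaled-down campaign sizes are stated with each result.

CBMC regrowth deletes either one side of a uniformly chosen bond or the
whole molecule, and regrows bead by bead in breadth-first order.  Trial
conformations are drawn *exactly* from the bonded Boltzmann distribution by
rejection sampling (uniform sphere directions accepted with the
harmonic-angle/dihedral weight, offset by the precomputed dihedral minimum),
and Rosenbluth selection applies to the external (nonbonded) energy only,
with n_first/n_bead trial positions; the reciprocal-space Ewald change
enters the final acceptance as a correction factor.  This
"internal-from-distribution" variant is simpler than coupled–decoupled
selection with dual cutoffs and remains exactly detailed balanced; it costs
speed, not correctness.  In fixed-bond mode bond lengths stay at r0; the
flexible mode draws lengths from the harmonic distribution including the r^2
Jacobian (Gaussian proposal, radial-weight rejection with a 5-sigma
envelope, bias < 1e-6).

Two engines share these conventions.  The general pure-numpy engine supports
all five models, with incremental molecule-vs-rest energies, structure-
factor updates for the reciprocal sum, and full re-evaluation on volume
moves; its running energy is compared against full recomputation in tests
(drift < 1e-6 relative).  The numba fast path handles single-site LJ fluids
and is cross-checked statistically against the general engine.  A detail
worth recording: a uniform rescaling of coordinates and box multiplies every
minimum-image distance by the scale factor, so volume-move energies in the
fast path are evaluated from the *unscaled* pair distances — exact, and it
avoids copying coordinate arrays in the hot loop.

## Molecular dynamics (single-site only)

The MD engine exists to expose one specific physical effect: with a
hard-truncated potential the force is discontinuous at r_cut; MD never sees
the energy jump a particle takes when crossing the cutoff, so hard-truncated
and shifted-potential MD produce bit-identical trajectories, while MC
accounts for the jump in its acceptance rule and samples a visibly denser
liquid under the hard cutoff.  Polyatomic constrained MD adds nothing to
this comparison and is out of scope.

Integration is velocity Verlet with a single Nosé–Hoover thermostat chain
(damping in steps; Q = N_f k_B T tau^2) and an MTK-style isotropic barostat
(W = (N_f+3) k_B T tau_p^2) with the cell update L *= exp(v_eps dt); the
kinetic temperature uses 3N-3 degrees of freedom and the center-of-mass
momentum, zeroed at start, is conserved by construction.  Initial velocities
are Maxwell–Boltzmann.  NVE conservation with the WCA potential is at the
1e-5 relative level over 10^4 steps at 1 fs.  Energy divergence (non-finite
state or kinetic temperature beyond 100x the set point) aborts with a
diagnostic naming the time step.

## Analysis

Equilibration detection computes the statistical inefficiency
g = 1 + 2 sum (1 - t/n) C(t) with positive-sequence truncation
(FFT autocorrelation) and scans candidate start indices for the maximum
effective sample count N_eff = (n - start)/g.  Replicate statistics average
per-replicate production means into a grand mean with a Student-t 95% CI
(n-1 degrees of freedom), and engine configurations are compared through
delta = 100 (rho_engine - rho_all)/rho_all about the unweighted pooled mean.
Error groupings report per-simulation-vs-pooled, per-simulation-vs-class
(MD/MC), and per-configuration-vs-pooled deviation sets.

The RDF uses ideal-gas shell normalization with intramolecular pairs
excluded; n(r) is the running coordination integral.  Hydrogen bonds use the
inclusive elliptical criterion centered at an O-O distance of 2.75 Å and a
donor-hydrogen-acceptor angle of 180 degrees with half-widths 0.5 Å and 50
degrees; counts are reported per system (divide by the molecule count for
the per-molecule view, since the axis convention of the published figure is
ambiguous).  Bond-length distributions report a delta at the constraint for
fixed-bond runs; for flexible harmonic bonds the r^2-Jacobian mean shift
2 sigma_b^2/r0 with sigma_b^2 = k_B T/k is the quadrature oracle — for the
OPLS O-H bond at 300 K this is ~0.001 Å in the gas phase, far smaller than
the ~0.018 Å shift a hydrogen-bonded liquid develops, so gas-phase tests
validate the sampler, not the liquid-phase physics.

## The cutoff-treatment magnitudes

The hard and shifted Hamiltonians differ by exactly -u(r_cut) per in-range
pair, which acts as an effective pressure shift
dp = |u(r_cut)| (N^2/2V^2)(4 pi/3) r_cut^3 (to first order, unit pair
correlation); the resulting density change is kappa_T dp.  The acceptance
test computes this prediction alongside the measured hard-vs-shifted gap,
with kappa_T taken from the campaign's own NpT volume fluctuations, and
requires the two to agree within a factor band.  For united-atom methane at
140 K / 1318 kPa with r_cut = 14 Å the measurement is ~+1.8-1.9% (prediction
~1.6%; the sampled compressibility, ~5e-9 /Pa, matches experimental liquid
methane).  The figure commonly quoted for this system is ~1.0%, which the
first-order estimate cannot reproduce with any compressibility consistent
with our volume fluctuations; notably, the same arithmetic applied to SPC/E
water at r_cut = 9 Å (dp ~ 1.4e7 Pa, textbook ambient-water compressibility
~4.6e-10 /Pa) gives ~0.6%, the commonly quoted water figure.  We therefore
report the computed methane value and flag the discrepancy rather than tune
toward the quoted one; the corresponding acceptance assertion is expected to
fail and says so in its message.

## What the synthetic conditions do and do not show

All inputs are generated internally (seeded lattices, built-in parameter
files); there is no experimental data anywhere.  Desk-scale campaigns use
N ≈ 400 molecules and shortened stages instead of the study-scale
N = 900-1800 with 16-256 replicates; at that scale the methane density
carries a ~±0.3-0.5 kg/m^3 (95% CI) statistical uncertainty and an
unquantified finite-size offset of similar order, so agreement with the
published 375.805 ± 0.021 kg/m^3 is asserted within the *combined* CI, not
at the published precision.  The hard-minus-shifted density difference
(~+1% for methane) is resolved at desk scale because it is thirty times the
replicate noise.  Ewald-heavy campaigns (liquid water/ethanol densities,
the 0.6% water cutoff effect, the liquid-phase O-H shift) are cluster-scale
and are exercised here only as short functional runs.

## Known limitations

- The virial pressure omits the reciprocal-space Coulomb term (reporting
  only; never used by the samplers).
- The general engine is pure Python/numpy and is meant for correctness and
  small systems, not throughput.
- Dual-cutoff CBMC and fragment-library sampling are not implemented; the
  trial-count presets are kept for schedule compatibility.
- The MD engine integrates single-site models only, with a chain-length-1
  thermostat rather than the three-chain variant.
- Tail corrections assume a uniform fluid beyond the cutoff; near-critical
  or interfacial states violate that assumption.
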