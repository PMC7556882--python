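# Methods

`mdasim` simulates identity-exchange sampling in a coarse-grained binary
lipid mixture and measures how much faster exchange moves equilibrate
lateral mixing than plain molecular dynamics. This note records the model,
the algorithms, the numerical choices, and what the built-in benchmarks do
and do not demonstrate.

## Model and units

Everything is in reduced units: the Lennard-Jones diameter of the reference
bead is the unit of length, its well depth the unit of energy, the bead
mass the unit of mass; temperatures are quoted as kT in energy units.
Presets that mirror a Martini-style parameterization use the conversion
sigma = 0.47 nm and epsilon = 3.5 kJ/mol, giving:

| preset                   | SI value      | reduced value |
|--------------------------|---------------|---------------|
| vdW / Coulomb cutoff     | 1.1 nm        | 2.34          |
| Coulomb prefactor        | 138.935 kJ mol^-1 nm e^-2 | 84.4 |
| dielectric screening     | 15            | 15            |
| temperature              | 335 K         | kT = 0.80     |
| soft-core delta          | 5.0 nm^2      | 22.6          |

The potential has three terms, tracked separately everywhere (the same
split the work analysis reports):

* **vdW** — 6-12 Lennard-Jones with a potential shift at the cutoff
  (continuous energy, so accumulated work contains no cutoff artifacts).
* **Coulomb** — reaction-field electrostatics: `C q_i q_j/eps_r (1/r +
  k_rf r^2 - c_rf)`, shifted to zero exactly at the cutoff;
  `eps_rf = infinity` (conductor boundary) by default.
* **Bonded** — harmonic bonds and *cosine-harmonic* angles,
  `U = k/2 (cos(theta) - cos(theta0))^2`. The cosine form is regular at the
  straight equilibrium geometry (theta0 = pi), where the plain harmonic
  angle force is singular.

Non-bonded interactions are excluded between beads of the same molecule.
Pairwise sums are all-pairs numba kernels with the minimum-image
convention; at the few hundred beads this package targets an evaluation
costs ~0.1-0.6 ms, so no neighbor-list machinery is used (results would
have to be identical anyway).

## Dynamics

NVT propagation uses velocity Verlet; one potential/force evaluation per
step, reused across the two half-kicks — which is what makes "force
evaluations" an honest cost unit. Thermostats:

* **Langevin** (default) via the BAOAB splitting; the O part is the exact
  Ornstein-Uhlenbeck update. `coupling` is the friction time 1/gamma.
* **Stochastic velocity rescaling** (canonical sampling through velocity
  rescaling) as the alternative mirroring common coarse-grained practice.

Default time step dt = 0.005 reduced time, a wide stability margin on the
steepest LJ wall at kT = 0.8. The harmonic-benchmark studies use dt = 0.02
with a unit-frequency well — small enough that the O(dt^2) sampling bias of
the splitting is far below the statistical resolution of the work
estimators.

## Exchange moves

An exchange swaps the identities of one molecule of each species. Only the
head bead differs between species (type, charge), so the move changes the
head-bead parameters of the selected pair and nothing else.

* **Single-step (MC-MD)**: dU = U(swapped) - U(current) at fixed
  coordinates, accepted with min(1, exp(-dU/kT)). Only the O(N) tagged-head
  interactions differ, so dU is one evaluation.
* **Alchemical trajectory (MDAS)**: the coupling parameter lambda runs
  0 -> 1 in increments `delta_lambda`, with M thermostatted MD steps at
  each fixed lambda. Work accumulates as the potential-energy jumps at the
  increments, evaluated at the instantaneous configuration; plateaus
  contribute no work. Acceptance is min(1, exp(-w/kT)). Accepted moves
  continue from the lambda = 1 phase-space point; rejected moves restore
  the pre-trajectory positions *and* velocities exactly (the trial runs on
  a copy). Velocities are never resampled at lambda increments — masses do
  not change, so the kinetic term cancels from the work.

Coupling: Coulomb terms always mix linearly between the endpoint
parameterizations, `U(lam) = (1-lam) U_A + lam U_B` (no particle vanishes,
so no soft-core is needed for charges). vdW terms mix linearly by default;
the soft-core form `4 eps lam (A^6 - A^3)`, `A = sigma^2/(r^2 +
delta (1-lam))` is available and is the right choice whenever an endpoint
bead has epsilon = 0 (a particle appearing or disappearing), since it stays
finite at overlap for lambda < 1 and reduces to plain LJ at lambda = 1.
The cutoff shift is applied uniformly to coupled and uncoupled terms.
When the two endpoints are identical the coupled terms are evaluated once
at full weight, which keeps the degenerate-exchange work exactly zero.

**Cost accounting.** Every MD step (plateau steps included) and every
lambda increment is one potential evaluation; a single-step exchange is
one. A full AT therefore costs `(M + 1)/delta_lambda`. The reference
schedule — 2000-step sampling segments and a 1000-step AT in which lambda
moves every tenth step (delta_lambda = 0.01, i.e. 100 windows of 9 plateau
steps + 1 increment) — costs exactly 3000 evaluations per MDAS attempt and
2001 per MC-MD attempt. The initial lambda = 0 energy is carried over from
the preceding segment's last step, not re-evaluated.

**Randomness.** A single root seed spawns named streams (build, dynamics
noise, pair selection, acceptance). Pair-selection and acceptance draws are
aligned between samplers, which is what makes the single-step equivalence
of MDAS(delta_lambda = 1, M = 0) and MC-MD checkable decision by decision.

## The toy membrane

A 2D monolayer of 3-bead linear lipids (head + 2 tails), two species
differing only in the head bead, plus explicit monovalent counterions; no
solvent beads — the Langevin friction is the implicit solvent. Defaults
(the package's study conditions):

* 50 + 50 lipids on a 10 x 10 molecule grid (350 beads with ions),
  box 19 x 36 sigma;
* head A: neutral, sigma = 1; head B: charge -0.5 e (one +0.5 counterion
  per charged lipid) and sigma = 1.1 — the charged head is slightly
  bulkier, so an instantaneous identity swap grows a bead inside a
  compressed neighbor cage and does steric work that a gradual trajectory
  relaxes away;
* unlike-head epsilon 1.25 versus 1.0 for like heads: the uniformly mixed
  state is the equilibrium the demixed start must relax to;
* Langevin friction gamma = 10 (coupling 0.1): a viscous implicit solvent,
  putting the system in the regime where lateral diffusion is slow
  relative to exchange moves;
* bonds k = 79, r0 = 1; angles k = 7, theta0 = pi (Martini-converted).

The demixed start places species A in the low-x half-box and B in the
high-x half (two interfaces under periodic boundaries), ions uniformly at
random, followed by a short displacement-capped steepest-descent burst that
removes build overlaps. The mixed reference assigns species to lattice
sites by a seeded uniform permutation.

What the generator does **not** emulate: explicit solvent structure and
hydrodynamics, bilayer (two-leaflet) geometry and flip-flop, area
fluctuations (constant-area NVT only), chain ordering/phase transitions,
and realistic Martini cross-interaction matrices. Passing benchmarks
demonstrate the correctness and relative efficiency of the samplers on a
system with the right qualitative physics (diffusion-limited mixing,
electrostatic + steric exchange work), not quantitative membrane biology.

## Mixing analysis

Mixing is monitored by the radial distribution function of same-species
head beads: demixed configurations have an elevated same-species g(r); as
the mixture equilibrates the tallest peak decays to the mixed plateau.
`max_gr_series` computes one g(r) per block of frames (default 5-10 frames
per block for variance reduction) and records the tallest peak at
r > 0.5 sigma (excluded-volume region masked out; search window up to
4 sigma in the benchmarks, where the structural peaks live). Bin width
default 0.05 sigma; the benchmarks use 0.1 sigma on 50-head selections.

`fit_exponential` fits `y = y_inf + a exp(-k t)` (t = cumulative force
evaluations) by bounded nonlinear least squares, with the time axis
rescaled to O(1) for conditioning. Rate initializations come from a
log-linear regression of the positive residuals and from a 1/e
first-crossing heuristic; the best-residual fit wins. Amplitudes are
constrained non-negative, so a non-decaying or constant series is reported
as a `FitError`, never returned silently. A known plateau (from an
equilibrated mixed reference) can be pinned with `fix_plateau`, which
stabilizes rates when a slow series has not fully converged. The speedup of
one sampler over another is the ratio of fitted rates, with first-order
error propagation from the fit covariances.

In the mixing benchmark the plateau is fixed from a *mixed-start MC-MD*
reference run: exchange sampling equilibrates composition in a few thousand
evaluations, whereas a plain-MD mixed reference retains slow structural
memory of the build lattice for much longer than it is worth simulating.

The acceptance estimate from exploratory work values is
`mean[min(1, exp(-w/kT))]` with a bootstrap standard error (default 1000
resamples) — useful when direct acceptance counting is impractical (e.g.
when almost nothing is accepted).

## Benchmark problem sizes

The standard studies (in `mdasim.benchmarks`, exercised by the test suite
and by `scripts/acceptance.py`) use: 10^6-move exchange-only chains on the
frozen 6-particle cluster (thinned by 20 for the chi-square comparison
against the 20 enumerated arrangements); 10^4 alchemical trajectories per
plateau length for the Jarzynski spring study (5000 in the acceptance
script); and ~1.5 x 10^5 production force evaluations per sampler for the
mixing benchmark (MD: 1200 125-step segments; MC-MD: 1200 attempts; MDAS:
600 attempts with a 130-evaluation AT, delta_lambda = 0.1, M = 12 — on
this toy the neighbor-cage relaxation is local and fast, so a short AT
already captures most of the work reduction), after a 20 000-step
equilibration burst whose cost is excluded from the production accounting.

## Known limitations

* 2D in-plane model only at scale; 3D is supported by the data structures
  and kernels but untested beyond unit level.
* All-pairs interaction kernels: O(N^2) per evaluation, fine for hundreds
  of beads, wrong tool for thousands.
* The MC-MD relaxation rate on the benchmark is often unresolvable — at
  ~126 evaluations per attempt the composition randomizes within the first
  few analysis blocks; the benchmark reports it only when its fit
  converges.
* One exchange pair per attempt; no multi-pair or inter-leaflet moves.
* No barostat; constant-area ensembles only.
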