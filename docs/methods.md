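# Methods

This note records the model, the numerical choices behind it, and what
the shipped tests do and do not demonstrate.

## Particle model

Peptides are rigid patchy spherocylinders: diameter σ = 2 nm, cylinder
length 8 nm (a 4:1 aspect chosen to mimic the elementary sheet unit of an
Aβ-scale peptide; both are configurable and every calibration property in
the test suite is either dimension-independent or expressed in σ). Each
particle carries one of two internal states:

| state | meaning | pair well | patch half-width |
|---|---|---|---|
| α | soluble random coil | −8.4 kBT | 90° |
| β | sheet conformation | −21 kBT  | 45° |

Cross-state attraction is the geometric mean (Berthelot), −13.28 kBT.
Converting a monomer α→β costs ΔG_int = 15 kBT, the value that keeps the
sheet state undetectable in solution. The patch widths are modelling
choices: the α patch is motivated by the hydrophobic surface fraction of
the coil form, the β patch must be narrower to make aggregate growth
directional. A smooth 10° shoulder outside each half-width keeps the
energy continuous for the samplers and optimizers.

### Pair potential

For axis–axis closest distance d (minimum-image):

- d < σ: hard core (+∞). Hard-core rejection rather than a soft
  repulsion makes the well-depth normalisation exact: the global pair
  minimum is −ε identically.
- σ ≤ d < r_c = 1.3 σ: E = −ε(s_a,s_b) · S(d) · g_a · g_b · w, with
  S(d) = cos²(π/2 · (d−σ)/(r_c−σ)) (unit value and zero slope at contact),
  g the per-particle angular gate (1 inside the patch half-width, cos²
  shoulder over 10°, 0 beyond) evaluated on the contact normal projected
  perpendicular to the particle axis, and w the mean axial-overlap
  fraction of the two segments (side-by-side parallel contact gives
  w = 1; crossed or end-to-end geometries are not attractive, which is
  what makes the stripe "run length-wise").
- d ≥ r_c: zero.

All factors lie in [0, 1], so −ε is a floor that the ideal side-by-side
contact attains exactly; this is what the pair-minimisation acceptance
check exploits. Chirality twists the gate direction linearly along the
axis (default 10° at the cylinder end); the flat gate top means the
centred ideal contact is unchanged, so the chiral and achiral pair minima
coincide while extended fibrils acquire a preferred twist (higher
persistence length). The achiral variant (`ModelParams.achiral()`) is
used wherever ideal reference configurations are needed.

### Ideal oligomer enthalpies

ΔH(i,k) is the global minimum interaction energy of i particles with k in
the β state. The optimizer searches planar arrangements of parallel
particles (centres + per-particle patch angles), seeded with the
candidate contact lattices (chain, triangle, square, rhombus, and for
pentamers house/brick/square-plus-tail shapes), refines patch angles by
joint pairwise grid descent — single-angle descent deadlocks because a
bond only pays off when both gates open — and polishes with Nelder–Mead,
including a full 3-D rigid-body polish. Results for the defaults are
exact bond-count identities (ε_aa = 8.4, ε_ab = 13.2816, ε_bb = 21):

    H(2,·) = −ε;  H(3,·): triangle, 3 bonds;
    H(4,0) = −5 ε_aa (rhombus, 5 contacts);
    H(4,4) = −4 ε_bb (square: the 45° sheet patch keeps only 4 contacts).

Under these patch widths *no* pure-state tetramer is iso-enthalpic with
its trimer: both states gain on the 3→4 step (α: −25.2→−42;
β: −63→−84). With a narrower sheet patch the β tetramer would lose its
square and degenerate to the trimer value; we record the computed result
rather than assuming either case.

## Dynamic Monte Carlo

- NVT, cubic periodic box; minimum-image convention (box > 2·(L+σ)
  enforced).
- One sweep = N attempted particle moves (particles drawn uniformly with
  replacement). Each attempt is, with probability p_switch, a state-flip
  proposal, otherwise a combined translation+rotation proposal.
  Acceptance is Metropolis on ΔE (+±ΔG_int for flips); rejected moves
  restore the particle bit-exactly.
- Move amplitudes are derived from the physical time mapping: one sweep
  ≈ 0.02 ns, and a free particle's mean-square displacement per sweep is
  matched to 6 D_t Δt with D_t = 1.5·10⁻¹⁰ m²/s (an Aβ-scale value; not
  an independently validated number — override it if you have a better
  one), giving a 0.173 nm displacement ball; rotations analogously from
  D_r = 2·10⁷ s⁻¹, giving a 0.069 rad cap. Both stay far below the σ/2
  bound that guarantees no unphysical tunnelling through contacts.
- p_switch defaults to 10⁻⁴ per particle move. Growth profiles are
  insensitive to an order of magnitude in either direction (tested at
  reduced scale), so the masked physical value does not need to be known
  precisely.
- Energies of a moved particle are evaluated against a Verlet neighbour
  list (radius L + r_c + 2 nm skin) rebuilt whenever any particle's
  accumulated centre+end drift exceeds half the skin.
- The initial condition is a non-overlapping random insertion of
  all-α monomers; a fixed-state β gas is available for the landscape
  runs (`initial_state="beta"`, p_switch = 0).
- Reproducibility: a run is a pure function of (config, model, seed);
  insertion and sweep streams are derived sub-seeds. All seeds are echoed
  into the output sidecars.

## Observables

Clusters are connected components of the bond graph; two particles are
bonded when their pair energy is below −1 kBT. The energy criterion
(rather than a distance) discounts glancing contacts; results should be
(and in the suite are) stable to ±50% changes of the cutoff. Aggregates
of ≥ 4 monomers count as fibrils; dimers+trimers form the "oligomer"
channel; the three channels conserve the initial monomer concentration
exactly by construction.

Half-times are the first crossing of half the plateau (mean of the final
10% of points, linearly interpolated). Residual monomer concentration is
the tail mean with a drift flag. Commitment probability of size-s
clusters tracks first-appearance clusters by >50% member overlap across
frames; a sub-fibril cluster commits on reaching fibril size, a
fibril-size cluster on doubling ("growing into a full fibre"), and
clusters unresolved at the trajectory end are excluded.

## Kinetics fitting

The Oosawa closed form is evaluated through logarithms
(sech^{2/n}(u) = exp((2/n)(log 2 − |u| − log1p e^{−2|u|}))) so it is
finite for arbitrarily large arguments. Fits minimise RSS on linear time
via bounded multi-start least squares over (n, log k_eff), n ∈ [1, 8];
ties break to the lower RSS then lower n. Every fit also profiles RSS
over fixed n, which is the single-curve degeneracy diagnostic: one
concentration constrains n hardly at all (RSS at n = 2 and n = 5 within
~20% on 5%-noise data), while a six-concentration global fit separates
both from the optimum by well over 5×. The half-time power law is fitted
by OLS in log–log space; n_scaling = −2·slope with the propagated
standard error. The residual report splits signed residuals at the
fitted half-time; predominantly positive early and negative late
residuals across all curves raise the systematic-deviation flag — the
signature of ring closure and fibril fusion, which remove growing ends
and are outside the closed-form theory.

## Free-energy landscape

F_i = −kBT ln(⟨N_i⟩/⟨N_1⟩) from the cluster populations of fixed-state
achiral runs at the working concentration (block-averaged errors; zero
counts give +∞ with a lower-bound flag). Per-monomer entropies
−T s(i) = (F_i − ΔH_i)/i; a lone particle's translational/rotational
entropy is state-independent in a rigid model, so s(1) ≡ 0 for both
states and the monomer conversion cost is exactly ΔG_int = 15 kBT — an
identity the suite asserts. Mixed-composition nodes assume each state's
per-monomer entropy is composition-independent. The nucleation path from
(1,0) to the first fully converted tetramer (4,4) allows α-monomer
addition and single conversions; the tiny lattice is enumerated
exhaustively and the minimax path (ordered free-energy key, deterministic
tie-break) is reported with its barrier node — the critical nucleus. A
pentamer column can be computed to check that the path keeps falling
beyond the tetramer.

## Validation scale and what it shows

The full study conditions (600 particles, six concentrations from 0.19
to 7.97 mM, ≥3 seeds each, ~2 µs of mapped time) reproduce the reference
kinetics but are an hours-long campaign. The shipped test suite instead
runs a reduced campaign chosen as the package's validation scale: 150
particles at 2/4/8 mM, three seeds per concentration, 6·10⁴ sweeps
(1.2 µs), run-averaged exactly as in the full protocol. At this scale the
curves are sigmoidal with monomer/oligomer depletion, tetramers commit to
fibril growth with probability ≈ 0.95–1 while dimers/trimers remain
dynamic, and the global fit and half-time slope give effective nucleus
sizes of ≈ 3.3 and ≈ 4.0.

Two caveats delimit what desk-scale passing shows. First, with the wide
coil patch the α-condensation branch is downhill beyond the dimer at
millimolar concentrations, and state conversion (rate
p_switch·e^{−ΔE} per move) is the slow step; reduced-scale fibrils are
therefore coil-rich — the condensation-first half of the
condensation–conversion pathway — whereas converting, sheet-rich fibrils
require the full-scale particle-sweep budget. Second, the landscape's
quantitative conversion costs (the dimer/trimer steps and the sub-kBT
barrier top) need full-scale fixed-state statistics; at desk scale the
suite asserts the structural identities instead (exact additivity of the
three components, the 15 kBT monomer anchor, and recovery of planted
cluster-size distributions within block-averaged errors).

The synthetic-curve generator produces exact closed-form kinetics with
multiplicative Gaussian noise on a log-spaced grid spanning 0.01–100
half-times. It emulates the shape and noise level of averaged growth
curves, not the correlated fluctuations or finite-size mass
quantisation of real (or simulated) assays, so fit-recovery tests
certify the estimator, not the simulator.

## Numerical details and degenerate inputs

- Segment–segment distance: clamped closed-form solver (region-wise
  projection); parallel segments take the symmetric midpoint branch;
  zero-length segments are rejected.
- End-on contacts have no defined side normal and are treated as
  non-attractive (gate 0).
- Overlapping configurations report +∞ total energy; the optimizers use
  a finite linear core penalty (200·(σ−d)/σ) instead so simplex steps
  across the contact boundary stay informed.
- Curves that never reach half their plateau, constant-zero fits,
  fewer than three scaling points, and missing entropy nodes all raise
  typed errors naming the offending quantity.
- All stochastic components (engine, synthetic noise, optimizers'
  multi-starts) are seeded; identical seeds give bit-identical
  trajectories and byte-identical CLI outputs.

## Known limitations

- No secondary nucleation, fragmentation, cluster moves or biased
  sampling: plain small-step single-particle DMC only.
- The fitted k_eff is reported in ns⁻¹·mM^{−n/2} via the 0.02 ns sweep
  mapping; the underlying diffusion constants are configurable inputs,
  not fitted quantities.
- Fibril morphology beyond ring/cycle flagging (persistence length,
  twist pitch) is out of scope.
- The landscape assumes ideal-configuration enthalpies and
  composition-independent per-monomer entropies; both are approximations
  that break down for large or strained aggregates.
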