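# Methods

This note documents the models and procedures implemented in `mlmmfe`, the
assumptions behind them, and the numerical choices that were genuinely open.

## The workflow in one paragraph

The binding free energy of a ligand is composed through a thermodynamic
cycle: classical alchemical decoupling of the ligand from the solvated
complex and from solution (estimated with MBAR over a ladder of
λ states), plus a correction at each physical end state for switching the
potential-energy surface from the molecular-mechanics (MM) description to a
hybrid ML/MM description, estimated from nonequilibrium (NEQ) switching work
with the Bennett acceptance ratio:

    ΔG_bind^MM    = ΔG_complex^MM − ΔG_solv^MM
    ΔG_bind^ML/MM = ΔG_complex^MM + ΔG_PL+S^ML/MM − ΔG_solv^MM − ΔG_L+S^ML/MM

The ML component is a second-generation high-dimensional neural-network
potential (HDNNP) over the QM region only, with electrostatic embedding
handled by charge-aware descriptors and an explicit Coulomb subtraction.

## Units

Energies kJ/mol, distances Å, charges e, forces kJ/mol/Å, time fs (MD) and
ps (protocols), masses amu, temperatures K. Coulomb constant
k_e = 1389.35457644 kJ Å mol⁻¹ e⁻²; k_B = 0.008314462618 kJ mol⁻¹ K⁻¹.
Open boundaries throughout; there is no periodic box and hence no
Ewald/PME — long-range electrostatics are summed directly.

## Learning target

The target is the QM-region energy plus its electrostatic interaction with
the environment, *minus* the full point-charge Coulomb sum between the
regions:

    E_ML = E_QM + E_elec^int − k_e Σ_{I∈Q} Σ_{A∈E} q_I q_A / r_IA

The subtraction removes the long-ranged part: what remains decays with
distance on the scale of the charge-redistribution (polarization) response,
so a local descriptor with a 5 Å cutoff suffices. QM atoms carry their MM
force-field charges for this subtraction. Forces are targeted for QM atoms
and for the MM atoms inside the cutoff shell E′; the 1 Å shell just outside
(E″) is computed and held out as a validation of the cutoff choice.

## Descriptors

Per-QM-atom element-embracing atom-centered symmetry functions with QM/MM
extensions. The radial structure function
F(r) = exp{η[1 − (1 − r²/r_c²)⁻¹]} doubles as the cutoff function: it and
all derivatives vanish smoothly at r_c. Small η gives wide Gaussians (long
range structure), large η narrow ones; since energies vary strongly with
bond lengths (~0.05 Å), the defaults span both regimes. The angular
function is (1/2 + λ/2·cos θ)^ζ.

Element identity enters through seven periodic-table channels per neighbor
— the constant 1, period n, main-group number m (fixed to 2 on the
d-block), d-column d, and the reversed counterparts n̄ = 6 − n, m̄ = 9 − m
(7 on the d-block), d̄ = 11 − d — each normalized by its maximum over the
supported set (periods 1–5, s/p/d blocks, i.e. H–Xe). The angular blocks
combine two neighbors' channels as normalized sums (γ = +1, all seven
channels) or shifted absolute differences (γ = −1, channels {1, n, m, d}),
eleven channels per (η, λ, ζ) combination. This 7/11 plan reproduces the
printed reference counts (35 radial / 132 angular / 167 for five η_rad,
two η_ang, two λ, three ζ) and is the package default; which four
difference channels the original count used is not derivable from the
counts alone, so the redundancy of difference channels over reversed
properties is accepted and documented here.

In QM/MM mode, interaction masks split every block by neighbor region: QM
neighbors contribute through element channels, MM neighbors only through
their point charge, normalized as q/(2 q_max) with q_max = 1 e by default.
Radial: 7 element channels (QM mask) + 1 charge channel (MM mask) per η.
Angular: 11 element channels (QM-QM), 7 element×charge channels (mixed,
slot-symmetric), 1 charge×charge channel (MM-MM) per combination.
Descriptor values are invariant to rotation, translation, and permutation
of identical atoms by construction; analytic Jacobians are verified against
central finite differences at relative error < 1e−6.

## Neural-network potential

One feed-forward subnetwork per chemical element — two tanh hidden layers,
linear output — maps a QM atom's (standardized) descriptor vector to an
atomic energy; the system energy is the sum over QM atoms, de-standardized
per atom count. Forces follow from the chain rule through the descriptor
Jacobians; atoms outside Q ∪ E′ receive exactly zero ML force.

Training minimizes w_E·MSE(energy per QM atom) + w_F·MSE(force components
over Q ∪ E′), defaults w_E : w_F = 1 : 0.1 but most experiments here use
1 : 0.05 (the force term has far more components and otherwise dominates).
The gradient of the force term needs d/dθ of dE/dG; it is computed exactly
by forward-over-reverse tangent propagation and verified against finite
differences. The optimizer is full-batch Adam with a geometric
learning-rate decay (default 1e−2, ×0.999 per epoch); a lifelong/continual
optimizer is out of scope and full retraining from the accumulated dataset
is used instead. Hidden widths default to 2√n_G rounded; the default split
is 90/10 by frame with a fixed seed. Training Jacobians are stored in
float32 (the ~1e−7 relative error is far below the force RMSE);
verification tests use float64.

Committees ("ensembles") of N_MLP ≥ 2 networks differ only in their
initialization seed. The committee energy is the member mean; its
uncertainty is max{floor, c·sample SD over members} with the floor set to
the members' mean test RMSE and calibration factor c = 1 by default. The
force analogue holds per component. The default committee size is 10;
desk-scale tests use 2–3 members (the uncertainty estimate is noisier but
unbiased, and the variance-reduction property of the mean holds for any
N ≥ 2).

## Training data

Base training sets are extracted from MM Langevin trajectories of the
physical end states with a time stride to reduce correlation, then
labelled by the reference oracle. Production potentials intended to *drive*
ML/MM dynamics are trained on a small temperature ladder
(300/450/600 K in equal shares by default in the workflow experiments):
configurations visited during mixed MM→ML/MM dynamics extend beyond the
300 K MM ensemble, and a potential fitted only to that ensemble can
extrapolate into spurious minima. Elevated-temperature sampling is the
standard low-cost way to broaden coverage; active learning then closes the
remaining gaps. The accuracy benchmarks in the test suite train on 300 K
end-state data (the stated sampling conditions).

## Toy reference system

A desk-scale stand-in for the QM/MM engine. The MM force field has harmonic
bonds E = ½k(r−r₀)² and angles ½k(θ−θ₀)², Lennard-Jones with
Lorentz–Berthelot combining and Coulomb over nonbonded pairs (1–2/1–3
excluded). The "QM" oracle for the six-atom ligand (elements C, O, H, S,
Cl; a Ru variant exercises the d-block) is

    E_oracle = E_intra-Q(bond/angle constants ×1.15) + E_Coul(Q↔E)
             + κ k_e Σ_{I∈Q} Σ_{A∈E} q_I q_A exp(−r_IA/r_pol)

with κ = 0.2 and r_pol = 2 Å < r_c. The force-constant perturbation
emulates an imperfect MM parameterization (a nonzero end-state correction
to switch off); the exponential polarization term emulates the
environment-induced response and is the only Q↔E coupling that survives
the Coulomb subtraction — so the learning target is strictly short-ranged,
which the tests verify both as an energy-insensitivity bound and as a
closed-form envelope on E″-shell forces. The solvent is monatomic charged
LJ particles placed ≥ 2.2 Å apart at liquid-like density. Solvent charges
are ±0.15 e: this puts a contact ion pair at ≈ 4 k_BT (300 K), giving a
polar-liquid-like structured-but-mobile environment; substantially larger
charges (e.g. ±0.4 e, ≈ 30 k_BT per contact pair) would turn the droplet
into a glassy ionic cluster whose sampling never converges on simulation
timescales. The
"complex" fixture adds a rigid 12-particle charged LJ pocket on an
icosahedron of radius 5 Å. What this toy does *not* emulate: real
electronic structure (charge transfer, many-body polarization),
molecular solvents with hydrogen-bond networks, conformational transitions
slower than the simulated timescales, and periodic solvation. Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery, not chemical accuracy on proteins.

## Dynamics and alchemistry

Langevin dynamics uses the BAOAB splitting (dt = 1 fs, friction 0.02–0.05
fs⁻¹, 300 K defaults); host-pocket atoms are frozen. Decoupling scales
ligand–environment Coulomb linearly in λ and LJ through a Beutler-style
soft core (r⁶ → r⁶ + α(1−λ)σ⁶, prefactor λ, α = 0.5), leaving intra-ligand
and environment terms untouched. The MM→ML/MM path is a linear mix
U(λ) = (1−λ)U_MM + λU_ML/MM, where U_ML/MM reassembles the committee-mean
ML energy with the analytic Q↔E Coulomb, the MM Q↔E LJ, and the MM
environment terms. λ schedules are linear in time; NEQ work is accumulated
stepwise over 100 segments per switch, W = Σ_k [U(λ_{k+1},x_k) −
U(λ_k,x_k)], with Langevin propagation between updates. Switch starting
frames are drawn from time-spaced equilibrium trajectories of each end
state. Desk-scale protocol defaults: 1 ps switches, 1 ps equilibration,
30 switches per direction; the cluster-scale 10 ps / 150-switch protocol is
a configuration choice away.

## Estimators

MBAR solves f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_k N_k exp(f_k − u_k(x_n)) in
the gauge f₁ = 0. The solver minimizes the equivalent convex objective
(L-BFGS with analytic gradient) and polishes with self-consistent
iteration to a residual of 1e−8; plain iteration alone converges too
slowly when state overlap is poor. The overlap diagnostic O_ij =
Σ_n W_ni N_j W_nj is row-stochastic. BAR solves the two-state
self-consistency over forward and (negated) backward work values by
bracketed root finding; the degenerate all-identical case is handled
exactly. The Jarzynski estimator is provided mainly as a consistency check
and flags its small-sample/broad-distribution bias. Statistical errors are
bootstrap (200 resamples by default), chosen over asymptotic covariances
because they remain meaningful for the short, correlated sample sets used
here. For MBAR the bootstrap resamples contiguous per-state blocks whose
length is the statistical inefficiency of that state's energy-difference
timeseries (initial-positive-sequence estimator), so serial correlation
widens rather than silently shrinks the error bar. For quantities governed
by modes slower than a single sampling window (solvent-shell occupancy in
the droplet), the replicate convention is used instead: independent
realizations with different seeds, mean ± scatter of the realization means.
Cycle errors add in quadrature.

An `ExactMLMMPotential` reassembles the ML/MM energy with the
analytic oracle in place of a fitted committee. It is the exact limit of
the learned potential and serves two purposes: a reference surface for
estimator-physics checks (where fitted-model extrapolation error would
confound the comparison) and a diagnostic baseline when debugging trained
committees.

## Active learning

Query-by-committee: during ML/MM-driven simulation, structures whose
committee disagreement exceeds 3× the energy or force RMSE floor are
collected; a greedy earliest-first selection with a minimum time gap
(0.05 ps default) and a per-iteration cap (25) thins them; the oracle
relabels the selection; the committee is retrained from scratch on the
grown dataset (1000 epochs per iteration by default). A run that flags
more structures than the cap is aborted for that iteration and no ΔG is
recorded. Convergence is declared when an iteration adds strictly fewer
than 10 structures (never on the 0th), after which a final 5000-epoch
retraining is performed. The exact thresholds, cap and spacing are
exposed configuration; the defaults are package choices.

## Problem sizes in the test suite

The test suite runs the whole pipeline at deliberately small sizes: the
solvated-ligand fixture with 20 solvent particles (26 atoms; 12 for the
active-learning replicates), reduced descriptor sets (~100 features),
hidden widths 12–16, committees of 2–3 members, ~2×10³ training
conformations for the accuracy benchmark, 1 ps switches × 30 repeats for
the NEQ consistency check (run on the exact oracle surface, so that the
check isolates the switching/estimator machinery from fitted-model error),
and 450-frame temperature-ladder base sets for the five-seed
active-learning convergence runs. These sizes are the package's desk-scale
reference configuration; every algorithmic path is identical at larger
sizes.

## Known limitations

- The committee uncertainty is a model-variance estimate; it cannot detect
  errors shared by all members (e.g. systematic descriptor blindness).
- Jarzynski estimates are biased for broad work distributions; BAR over
  both directions is the default for end-state corrections.
- No periodic boundaries: solvation is a finite droplet, and decoupled
  ligands see a vacuum, not a standard-state volume; free energies are
  internally consistent but not standard-state corrected.
- f-block elements and formal-charge bookkeeping are unsupported.
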