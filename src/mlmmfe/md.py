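"""Langevin dynamics, alchemical potentials, and nonequilibrium switching.

Dynamics use the BAOAB splitting of the Langevin equation (kick - drift -
thermostat - drift - kick), which samples configuration space accurately at
moderate time steps. Host atoms (the rigid pocket of the complex fixture)
are frozen through a movable mask.

Two alchemical modes are provided. ``decouple_ligand`` scales the
ligand-environment interactions: Coulomb linearly in lambda, LJ through a
Beutler-style soft core (the r^6 term shifted by alpha*(1-lambda)*sigma^6)
so that no singularity appears as particles overlap near lambda = 0.
``mm_to_mlmm`` interpolates linearly between the MM potential and the ML/MM
potential, in which the learned energy replaces the intra-ligand MM terms
and the ligand-environment electrostatics are re-added analytically.

Nonequilibrium switching accumulates work stepwise over a discrete schedule,
W = sum_k [U(lambda_{k+1}, x_k) - U(lambda_k, x_k)], propagating with
Langevin dynamics between lambda updates. High-uncertainty structures
encountered while the ML potential is driving the dynamics can be collected
for active learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ACCEL_UNIT, BOLTZMANN_CONSTANT
from .elements import ATOMIC_MASSES
from .estimators import ReducedEnergyMatrix
from .nnp import EnsembleModel
from .system import AtomicSystem, coulomb_qm_mm, partition_regions
from .toy import ToyForceField, ToyTopology, _pair_energy_forces

__all__ = [
    "LangevinParams",
    "AlchemicalState",
    "SwitchProtocol",
    "WorkRecord",
    "Trajectory",
    "MMPotential",
    "MLMMPotential",
    "MixedPotential",
    "DecoupledMMPotential",
    "ExactMLMMPotential",
    "UncertaintyCollector",
    "alchemical_potential",
    "run_md",
    "sample_afe_states",
    "run_neq_switch",
    "neq_work_set",
]


@dataclass
class LangevinParams:
    dt: float = 1.0            # fs
    friction: float = 0.02     # fs^-1
    temperature: float = 300.0  # K
    seed: int = 0
    masses: np.ndarray | None = None  # amu, else from elements

    def __post_init__(self):
        if self.dt <= 0 or self.friction < 0 or self.temperature <= 0:
            raise ValueError("invalid Langevin parameters")


@dataclass(frozen=True)
class AlchemicalState:
    lam: float
    softcore_alpha: float = 0.5
    mode: str = "decouple_ligand"  # or "mm_to_mlmm"

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.mode not in ("decouple_ligand", "mm_to_mlmm"):
            raise ValueError(f"unknown alchemical mode {self.mode!r}")


@dataclass
class SwitchProtocol:
    t_switch: float = 1.0      # ps; 0 means an instantaneous jump
    t_equil: float = 1.0       # ps
    n_switches: int = 30
    n_segments: int = 100
    schedule: object = None    # callable s in [0,1] -> lambda; default linear

    def __post_init__(self):
        if self.t_switch < 0 or self.n_switches < 1 or self.n_segments < 1:
            raise ValueError("invalid switch protocol")

    def lam(self, s: float) -> float:
        if self.schedule is None:
            return float(s)
        lam = float(self.schedule(s))
        if not 0.0 <= lam <= 1.0:
            raise ValueError("schedule left [0, 1]")
        return lam


@dataclass
class WorkRecord:
    direction: str             # "forward" | "backward"
    work: float                # kJ/mol
    seed: int
    start_frame: int = -1

    def __post_init__(self):
        if not np.isfinite(self.work):
            raise ValueError("non-finite work")


@dataclass
class Trajectory:
    positions: np.ndarray      # (n_frames, n_atoms, 3)
    times: np.ndarray          # fs
    final_positions: np.ndarray
    final_velocities: np.ndarray
    velocities: np.ndarray | None = None  # (n_frames, n_atoms, 3), Å/fs

    def __len__(self):
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

class MMPotential:
    """Full MM potential of a toy system."""

    def __init__(self, template: AtomicSystem, topology: ToyTopology):
        self.template = template
        self.ff = ToyForceField(topology)

    def energy_forces(self, positions: np.ndarray):
        return self.ff.energy_forces(self.template.with_positions(positions))


class UncertaintyCollector:
    """Gathers structures whose committee disagreement exceeds thresholds.

    Thresholds are multiples of the ensemble's RMSE floors. Entries carry a
    running evaluation index that callers translate into simulation time.
    """

    def __init__(self, energy_threshold: float = 3.0,
                 force_threshold: float = 3.0):
        if energy_threshold <= 1.0 or force_threshold <= 1.0:
            raise ValueError("thresholds are multiples of the floor, > 1")
        self.energy_threshold = energy_threshold
        self.force_threshold = force_threshold
        self.records: list[dict] = []
        self._counter = 0

    def observe(self, positions, e_unc, f_unc_max, floors):
        self._counter += 1
        floor_e, floor_f = floors
        if (e_unc > self.energy_threshold * floor_e
                or f_unc_max > self.force_threshold * floor_f):
            self.records.append({
                "positions": positions.copy(),
                "eval_index": self._counter,
                "energy_uncertainty": e_unc,
                "force_uncertainty": f_unc_max,
            })


class MLMMPotential:
    """ML/MM potential: learned QM-region energy + analytic MM remainder.

    U = E_ML(ensemble mean) + E_Coul(Q<->E) + E_LJ(Q<->E) + E_MM(environment).
    """

    def __init__(self, template: AtomicSystem, topology: ToyTopology,
                 ensemble: EnsembleModel,
                 collector: UncertaintyCollector | None = None):
        self.template = template
        self.topology = topology
        self.ff = ToyForceField(topology)
        self.ensemble = ensemble
        self.collector = collector

    def energy_forces(self, positions: np.ndarray):
        system = self.template.with_positions(positions)
        partition = partition_regions(system, self.ensemble.config.r_cut)
        e_ml, de, f_ml, df = self.ensemble.predict(system, partition)
        if self.collector is not None:
            self.collector.observe(positions, de, float(df.max()),
                                   (self.ensemble.rmse_floor_energy,
                                    self.ensemble.rmse_floor_force))
        e_coul, f_coul = coulomb_qm_mm(system)
        comp = self.ff.components(system)
        energy = e_ml + e_coul + comp["qe_lj"][0] + comp["env"][0]
        forces = f_ml + f_coul + comp["qe_lj"][1] + comp["env"][1]
        return energy, forces


class ExactMLMMPotential:
    """ML/MM reassembly with the analytic oracle in place of a fitted model.

    U = E_oracle + E_LJ(Q<->E) + E_MM(environment); the oracle already
    contains the intra-QM terms, the Q<->E Coulomb sum and the polarization
    response. This is the exact limit of :class:`MLMMPotential` and serves
    as the reference surface for estimator-consistency checks and as a
    diagnostic baseline for trained committees.
    """

    def __init__(self, template: AtomicSystem, topology: ToyTopology,
                 oracle_params):
        from .toy import toy_qm_oracle
        self._oracle = toy_qm_oracle
        self.template = template
        self.topology = topology
        self.oracle_params = oracle_params
        self.ff = ToyForceField(topology)

    def energy_forces(self, positions: np.ndarray):
        system = self.template.with_positions(positions)
        e, f = self._oracle(system, self.topology, self.oracle_params)
        comp = self.ff.components(system)
        return (e + comp["qe_lj"][0] + comp["env"][0],
                f + comp["qe_lj"][1] + comp["env"][1])


class MixedPotential:
    """Affine interpolation U(lambda) = (1-lambda) U0 + lambda U1."""

    def __init__(self, pot0, pot1, lam: float):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.pot0, self.pot1, self.lam = pot0, pot1, lam

    def endpoint_energies(self, positions):
        e0, _ = self.pot0.energy_forces(positions)
        e1, _ = self.pot1.energy_forces(positions)
        return e0, e1

    def energy_forces(self, positions):
        e0, f0 = self.pot0.energy_forces(positions)
        e1, f1 = self.pot1.energy_forces(positions)
        lam = self.lam
        return (1 - lam) * e0 + lam * e1, (1 - lam) * f0 + lam * f1


class DecoupledMMPotential:
    """MM potential with ligand-environment interactions scaled by lambda.

    Coulomb scales linearly; LJ uses the soft-core form. Intra-ligand and
    environment-environment terms are untouched. lambda = 1 is the fully
    interacting system, lambda = 0 the ligand in vacuum beside the intact
    environment.
    """

    def __init__(self, template: AtomicSystem, topology: ToyTopology,
                 lam: float, softcore_alpha: float = 0.5):
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        self.template = template
        self.ff = ToyForceField(topology)
        self.lam = lam
        self.alpha = softcore_alpha
        is_qm = template.regions == "QM"
        pi, pj, eps, sig, qq = self.ff.pair_arrays()
        cross = is_qm[pi] ^ is_qm[pj]
        self._cross = (pi[cross], pj[cross], eps[cross], sig[cross], qq[cross])
        self._keep = ~cross

    def energy_forces(self, positions: np.ndarray):
        system = self.template.with_positions(positions)
        pos = system.positions
        forces = np.zeros_like(pos)
        top = self.ff.top
        from .toy import _angle_energy_forces, _bond_energy_forces
        e = _bond_energy_forces(pos, top.bonds, top.bond_k, top.bond_r0, forces)
        e += _angle_energy_forces(pos, top.angles, top.angle_k,
                                  top.angle_theta0, forces)
        pi, pj, eps, sig, qq = self.ff.pair_arrays()
        k = self._keep
        el, ec = _pair_energy_forces(pos, pi[k], pj[k], eps[k], sig[k],
                                     qq[k], forces)
        e += el + ec
        cpi, cpj, ceps, csig, cqq = self._cross
        el, ec = _pair_energy_forces(pos, cpi, cpj, ceps, csig,
                                     cqq * self.lam, forces,
                                     lj_lambda=self.lam,
                                     softcore_alpha=self.alpha)
        return e + el + ec, forces


def alchemical_potential(state: AlchemicalState, template: AtomicSystem,
                         topology: ToyTopology,
                         ensemble: EnsembleModel | None = None,
                         collector: UncertaintyCollector | None = None):
    """Build the energy/forces callable for an alchemical state."""
    if state.mode == "decouple_ligand":
        return DecoupledMMPotential(template, topology, state.lam,
                                    state.softcore_alpha)
    if ensemble is None:
        raise ValueError("mm_to_mlmm requires a fitted ensemble")
    mm = MMPotential(template, topology)
    mlmm = MLMMPotential(template, topology, ensemble, collector)
    return MixedPotential(mm, mlmm, state.lam)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _masses_for(system: AtomicSystem, params: LangevinParams) -> np.ndarray:
    if params.masses is not None:
        return np.asarray(params.masses, dtype=float)
    return np.array([ATOMIC_MASSES[e] for e in system.elements])


def run_md(system: AtomicSystem, potential, params: LangevinParams,
           n_steps: int, stride: int = 10,
           movable: np.ndarray | None = None,
           velocities: np.ndarray | None = None) -> Trajectory:
    """BAOAB Langevin dynamics; deterministic for a given seed.

    ``movable`` marks atoms that propagate (defaults to all); frozen atoms
    keep their coordinates and exert forces as static scatterers.
    """
    rng = np.random.default_rng(params.seed)
    pos = system.positions.copy()
    n = pos.shape[0]
    m = _masses_for(system, params)[:, None]
    mov = np.ones(n, bool) if movable is None else np.asarray(movable, bool)
    kt = BOLTZMANN_CONSTANT * params.temperature
    sigma_v = np.sqrt(kt / m * ACCEL_UNIT)
    if velocities is None:
        vel = sigma_v * rng.standard_normal((n, 3))
    else:
        vel = velocities.copy()
    vel[~mov] = 0.0
    c1 = np.exp(-params.friction * params.dt)
    c2 = np.sqrt(1.0 - c1 ** 2)
    dt = params.dt
    e, f = potential.energy_forces(pos)
    frames, times, vels = [], [], []
    for step in range(n_steps):
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite force at step {step}")
        vel[mov] += 0.5 * dt * f[mov] / m[mov] * ACCEL_UNIT
        pos[mov] += 0.5 * dt * vel[mov]
        if params.friction > 0:
            vel[mov] = c1 * vel[mov] + c2 * sigma_v[mov] \
                * rng.standard_normal((int(mov.sum()), 3))
        pos[mov] += 0.5 * dt * vel[mov]
        e, f = potential.energy_forces(pos)
        vel[mov] += 0.5 * dt * f[mov] / m[mov] * ACCEL_UNIT
        if (step + 1) % stride == 0:
            frames.append(pos.copy())
            vels.append(vel.copy())
            times.append((step + 1) * dt)
    return Trajectory(np.array(frames).reshape(len(frames), n, 3),
                      np.array(times), pos, vel,
                      np.array(vels).reshape(len(frames), n, 3))


# ---------------------------------------------------------------------------
# equilibrium lambda sampling and NEQ switching
# ---------------------------------------------------------------------------

def sample_afe_states(system: AtomicSystem, make_potential, lambdas,
                      params: LangevinParams, n_samples: int,
                      n_equil_steps: int = 200, stride: int = 10,
                      movable: np.ndarray | None = None) -> ReducedEnergyMatrix:
    """Equilibrium sampling at each lambda state, cross-evaluated for MBAR.

    ``make_potential(lam)`` builds the state potential. Every sampled frame
    is evaluated under every state's reduced energy u_k = U_k / k_B T.
    Affine paths (potentials exposing ``endpoint_energies``) are evaluated
    from the two endpoint energies only.
    """
    lambdas = list(lambdas)
    if len(lambdas) < 2:
        raise ValueError("need at least two lambda states")
    kt = BOLTZMANN_CONSTANT * params.temperature
    pots = [make_potential(lam) for lam in lambdas]
    all_frames, counts = [], []
    # each state equilibrates independently from the input configuration:
    # chaining states hands each one the previous state's bias
    for k, pot in enumerate(pots):
        p = LangevinParams(params.dt, params.friction, params.temperature,
                           params.seed + 1000 * k, params.masses)
        eq = run_md(system, pot, p, n_equil_steps,
                    stride=max(1, n_equil_steps), movable=movable)
        p2 = LangevinParams(params.dt, params.friction, params.temperature,
                            params.seed + 1000 * k + 1, params.masses)
        traj = run_md(system.with_positions(eq.final_positions), pot, p2,
                      n_samples * stride, stride=stride, movable=movable,
                      velocities=eq.final_velocities)
        all_frames.extend(traj.positions)
        counts.append(len(traj))
    affine = all(hasattr(p, "endpoint_energies") for p in pots)
    u = np.empty((len(lambdas), len(all_frames)))
    for n_i, x in enumerate(all_frames):
        if affine:
            e0, e1 = pots[0].endpoint_energies(x)
            for k, lam in enumerate(lambdas):
                u[k, n_i] = ((1 - lam) * e0 + lam * e1) / kt
        else:
            for k, pot in enumerate(pots):
                u[k, n_i] = pot.energy_forces(x)[0] / kt
    return ReducedEnergyMatrix(u, np.array(counts), params.temperature)


def run_neq_switch(start_positions: np.ndarray, protocol: SwitchProtocol,
                   direction: str, make_potential, system: AtomicSystem,
                   params: LangevinParams, movable: np.ndarray | None = None,
                   start_frame: int = -1) -> WorkRecord:
    """One nonequilibrium switch with stepwise work accumulation.

    ``make_potential(lam)`` builds the driving potential. ``forward`` runs
    lambda 0 -> 1, ``backward`` 1 -> 0. The work is the sum of potential
    jumps at the lambda updates; propagation happens between updates.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if protocol.t_switch > 0:
        n_steps_total = max(protocol.n_segments,
                            int(round(protocol.t_switch * 1000.0 / params.dt)))
        seg_steps = max(1, n_steps_total // protocol.n_segments)
    else:
        seg_steps = 0
    svals = np.linspace(0.0, 1.0, protocol.n_segments + 1)
    lams = np.array([protocol.lam(s) for s in svals])
    if direction == "backward":
        lams = lams[::-1]
    pots = {lam: make_potential(lam) for lam in np.unique(lams)}
    pos = start_positions.copy()
    vel = None
    work = 0.0
    for k in range(protocol.n_segments):
        if seg_steps > 0 and protocol.t_switch > 0:
            p = LangevinParams(params.dt, params.friction, params.temperature,
                               params.seed + 7 * k + 1, params.masses)
            traj = run_md(system.with_positions(pos), pots[lams[k]], p,
                          seg_steps, stride=seg_steps, movable=movable,
                          velocities=vel)
            pos, vel = traj.final_positions, traj.final_velocities
        pot_k = pots[lams[k]]
        if hasattr(pot_k, "endpoint_energies"):  # affine path: one evaluation
            e0, e1 = pot_k.endpoint_energies(pos)
            work += (lams[k + 1] - lams[k]) * (e1 - e0)
        else:
            work += (pots[lams[k + 1]].energy_forces(pos)[0]
                     - pot_k.energy_forces(pos)[0])
    return WorkRecord(direction, float(work), params.seed, start_frame)


def neq_work_set(make_potential, system: AtomicSystem,
                 start_frames_forward, start_frames_backward,
                 protocol: SwitchProtocol, params: LangevinParams,
                 movable: np.ndarray | None = None):
    """Forward and backward work sets over pools of equilibrated start frames."""
    fwd, bwd = [], []
    nf = len(start_frames_forward)
    nb = len(start_frames_backward)
    for s in range(protocol.n_switches):
        p = LangevinParams(params.dt, params.friction, params.temperature,
                           params.seed + 100000 + 997 * s, params.masses)
        fwd.append(run_neq_switch(start_frames_forward[s % nf], protocol,
                                  "forward", make_potential, system, p,
                                  movable, start_frame=s % nf))
        p = LangevinParams(params.dt, params.friction, params.temperature,
                           params.seed + 200000 + 997 * s, params.masses)
        bwd.append(run_neq_switch(start_frames_backward[s % nb], protocol,
                                  "backward", make_potential, system, p,
                                  movable, start_frame=s % nb))
    return fwd, bwd
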