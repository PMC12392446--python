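"""Query-by-committee active learning for the ML/MM potential.

Structures visited during ML/MM-driven simulations whose committee
disagreement exceeds a multiple of the ensemble's test-RMSE floor are
collected, thinned by a minimum time separation (to avoid strongly
correlated duplicates), relabelled by the reference oracle, and added to the
training set; the committee is then retrained from scratch on the grown set.
The loop has converged when an iteration contributes fewer new structures
than the convergence count, after which a final, longer retraining is
performed. If a simulation accumulates more flagged structures than the
per-iteration cap it is aborted early — the potential is clearly not yet
trustworthy there — and no free-energy estimate is recorded for that
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorConfig
from .estimators import bar_from_work
from .md import (LangevinParams, MLMMPotential, MMPotential, SwitchProtocol,
                 UncertaintyCollector, MixedPotential, neq_work_set, run_md)
from .nnp import EnsembleFitResult, HDNNPEnsemble, TrainingDataset
from .system import AtomicSystem
from .toy import OracleParams, ToyTopology
from .workflow import frame_from_system, movable_mask

__all__ = [
    "ALConfig",
    "ALState",
    "flag_uncertain",
    "select_spaced",
    "has_converged",
    "ActiveLearner",
]


@dataclass
class ALConfig:
    energy_threshold: float = 3.0      # multiple of the energy RMSE floor
    force_threshold: float = 3.0       # multiple of the force RMSE floor
    min_time_separation: float = 0.05  # ps
    per_iteration_cap: int = 25
    convergence_new_structures: int = 10
    base_epochs: int = 1000
    final_epochs: int = 5000
    max_iterations: int = 10
    n_repeats: int = 6                 # repeated NEQ dG estimates per iteration

    def __post_init__(self):
        if self.energy_threshold <= 1.0 or self.force_threshold <= 1.0:
            raise ValueError("uncertainty thresholds must exceed 1x the floor")
        if self.per_iteration_cap < 1 or self.convergence_new_structures < 0:
            raise ValueError("invalid cap/convergence count")


@dataclass
class ALState:
    """Progress of the active-learning loop."""

    dataset: TrainingDataset
    iteration: int = 0
    flagged_counts: list = field(default_factory=list)
    selected_counts: list = field(default_factory=list)
    added_counts: list = field(default_factory=list)
    dg_estimates: list = field(default_factory=list)  # (dg, err) or None
    aborted: list = field(default_factory=list)
    seen_ids: set = field(default_factory=set)

    def __post_init__(self):
        self.seen_ids |= {f.frame_id for f in self.dataset.frames}


def flag_uncertain(trajectory, ensemble, config: ALConfig,
                   template: AtomicSystem | None = None) -> list[dict]:
    """Frames of a trajectory whose committee uncertainty exceeds thresholds.

    ``trajectory`` is either an md.Trajectory (requires ``template``) or an
    iterable of dicts with ``positions`` and ``time_ps`` keys.
    """
    records = []
    if hasattr(trajectory, "positions") and template is not None:
        it = ({"positions": p, "time_ps": t / 1000.0}
              for p, t in zip(trajectory.positions, trajectory.times))
    else:
        it = iter(trajectory)
    for rec in it:
        system = template.with_positions(rec["positions"]) if template \
            else rec["system"]
        _, de, _, df = ensemble.predict(system)
        if (de > config.energy_threshold * ensemble.rmse_floor_energy
                or float(df.max()) > config.force_threshold
                * ensemble.rmse_floor_force):
            records.append({**rec, "energy_uncertainty": de,
                            "force_uncertainty": float(df.max())})
    return records


def select_spaced(flagged: list[dict], min_time_separation: float,
                  cap: int) -> list[dict]:
    """Greedy earliest-first thinning with a minimum time gap (ps)."""
    out = []
    last = -np.inf
    for rec in sorted(flagged, key=lambda r: r["time_ps"]):
        if rec["time_ps"] - last >= min_time_separation:
            out.append(rec)
            last = rec["time_ps"]
            if len(out) >= cap:
                break
    return out


def has_converged(state: ALState, config: ALConfig) -> bool:
    """True once an iteration has added strictly fewer than the threshold."""
    if state.iteration < 1 or not state.added_counts:
        return False
    return state.added_counts[-1] < config.convergence_new_structures


class ActiveLearner:
    """Runs the collect - relabel - retrain loop on a toy system.

    Each iteration drives nonequilibrium MM -> ML/MM switching with the
    current committee while collecting high-uncertainty structures, then
    relabels a time-spaced selection with the oracle and retrains.
    """

    def __init__(self, template: AtomicSystem, topology: ToyTopology,
                 oracle_params: OracleParams, dataset: TrainingDataset,
                 al_config: ALConfig, md_params: LangevinParams,
                 protocol: SwitchProtocol, hidden=None, n_members: int = 2,
                 loss_weights=(1.0, 0.1), lr: float = 5e-3, seed: int = 0):
        self.template = template
        self.topology = topology
        self.oracle_params = oracle_params
        self.al_config = al_config
        self.md_params = md_params
        self.protocol = protocol
        self.hidden = hidden
        self.n_members = n_members
        self.loss_weights = loss_weights
        self.lr = lr
        self.seed = seed
        self.state = ALState(dataset)
        self.fit_result: EnsembleFitResult | None = None
        self._next_id = max(self.state.seen_ids, default=-1) + 1

    # -- training -----------------------------------------------------
    def train(self, epochs: int) -> EnsembleFitResult:
        model = HDNNPEnsemble(self.state.dataset, hidden=self.hidden,
                              n_members=self.n_members)
        self.fit_result = model.fit(epochs=epochs, seed=self.seed,
                                    loss_weights=self.loss_weights, lr=self.lr)
        return self.fit_result

    # -- one iteration ------------------------------------------------
    def iterate(self) -> ALState:
        if self.fit_result is None:
            self.train(self.al_config.base_epochs)
        ensemble = self.fit_result.ensemble
        cfg = self.al_config
        collector = UncertaintyCollector(cfg.energy_threshold,
                                         cfg.force_threshold)
        mov = movable_mask(self.topology)
        mm = MMPotential(self.template, self.topology)
        mlmm = MLMMPotential(self.template, self.topology, ensemble,
                             collector)

        def make_potential(lam):
            return MixedPotential(mm, mlmm, lam)

        it_seed = self.seed + 31 * (self.state.iteration + 1)
        p = LangevinParams(self.md_params.dt, self.md_params.friction,
                           self.md_params.temperature, it_seed,
                           self.md_params.masses)
        # equilibrate both end states for switch starting frames
        eq0 = run_md(self.template, mm, p,
                     int(self.protocol.t_equil * 1000 / p.dt) or 1,
                     stride=10**9, movable=mov)
        aborted = False
        try:
            eq1 = run_md(self.template.with_positions(eq0.final_positions),
                         mlmm, p,
                         int(self.protocol.t_equil * 1000 / p.dt) or 1,
                         stride=10**9, movable=mov)
            start1 = eq1.final_positions
        except FloatingPointError:
            aborted = True
            start1 = eq0.final_positions
        works_f = works_r = None
        if not aborted and len(collector.records) <= cfg.per_iteration_cap:
            try:
                works_f, works_r = neq_work_set(
                    make_potential, self.template, [eq0.final_positions],
                    [start1], self.protocol, p, movable=mov)
            except FloatingPointError:
                aborted = True
        if len(collector.records) > cfg.per_iteration_cap:
            aborted = True  # too many flagged structures: stop simulating
        # translate evaluation indices into time stamps
        flagged = [{
            "positions": r["positions"],
            "time_ps": r["eval_index"] * self.md_params.dt / 1000.0,
            "energy_uncertainty": r["energy_uncertainty"],
            "force_uncertainty": r["force_uncertainty"],
        } for r in collector.records]
        selected = select_spaced(flagged, cfg.min_time_separation,
                                 cfg.per_iteration_cap)
        added = 0
        for rec in selected:
            try:
                frame = frame_from_system(
                    self.template.with_positions(rec["positions"]),
                    self.topology, self.oracle_params,
                    self.state.dataset.config, frame_id=self._next_id)
            except Exception:  # oracle failure: skip the frame
                continue
            if frame.frame_id in self.state.seen_ids:
                continue
            self.state.dataset.frames.append(frame)
            self.state.seen_ids.add(frame.frame_id)
            self._next_id += 1
            added += 1
        if added:
            self.state.dataset = TrainingDataset(
                self.state.dataset.frames, self.state.dataset.config,
                split_seed=self.seed)
            self.train(cfg.base_epochs)
        dg = None
        if works_f is not None and not aborted:
            r = bar_from_work(works_f, works_r, p.temperature,
                              n_bootstrap=50, seed=it_seed)
            dg = (r.delta_g, r.stat_error)
        self.state.iteration += 1
        self.state.flagged_counts.append(len(flagged))
        self.state.selected_counts.append(len(selected))
        self.state.added_counts.append(added)
        self.state.dg_estimates.append(dg)
        self.state.aborted.append(aborted)
        return self.state

    # -- checkpointing ------------------------------------------------
    def save_state(self, path):
        """Resumable checkpoint: the grown dataset plus loop bookkeeping."""
        import json

        import h5py

        from .io import save_dataset
        save_dataset(path, self.state.dataset)
        meta = {
            "iteration": self.state.iteration,
            "flagged_counts": self.state.flagged_counts,
            "selected_counts": self.state.selected_counts,
            "added_counts": self.state.added_counts,
            "dg_estimates": self.state.dg_estimates,
            "aborted": self.state.aborted,
            "next_id": self._next_id,
        }
        with h5py.File(path, "a") as fh:
            fh.attrs["al_state"] = json.dumps(meta)

    def restore_state(self, path):
        import json

        import h5py

        from .io import load_dataset
        dataset = load_dataset(path)
        with h5py.File(path, "r") as fh:
            meta = json.loads(fh.attrs["al_state"])
        self.state = ALState(dataset)
        self.state.iteration = meta["iteration"]
        self.state.flagged_counts = meta["flagged_counts"]
        self.state.selected_counts = meta["selected_counts"]
        self.state.added_counts = meta["added_counts"]
        self.state.dg_estimates = [None if d is None else tuple(d)
                                   for d in meta["dg_estimates"]]
        self.state.aborted = meta["aborted"]
        self._next_id = meta["next_id"]
        self.fit_result = None  # retrain from the restored dataset

    # -- full loop ----------------------------------------------------
    def run(self) -> ALState:
        self.train(self.al_config.base_epochs)
        while (self.state.iteration < self.al_config.max_iterations
               and not has_converged(self.state, self.al_config)):
            self.iterate()
        if has_converged(self.state, self.al_config):
            self.train(self.al_config.final_epochs)
        return self.state
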