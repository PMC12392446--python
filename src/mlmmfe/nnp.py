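"""High-dimensional neural-network potential on QM/MM descriptors.

The potential energy of the QM region is a sum of atomic energies, one
feed-forward subnetwork per chemical element, evaluated on that atom's
descriptor vector. Networks have two hidden tanh layers and a linear output.
Forces follow from the chain rule through the analytic descriptor Jacobians;
MM atoms beyond the cutoff of every QM atom receive exactly zero ML force.

Training minimizes a weighted sum of the per-QM-atom energy MSE and the
force-component MSE over the QM region and the in-cutoff MM shell E'.
Gradients of the force loss require second derivatives of the network
(d/d-params of dE/d-inputs); these are computed exactly with a
forward-over-reverse tangent propagation, vectorized over atoms.

Committees of identically trained, differently initialized networks provide
the prediction and its uncertainty: the ensemble energy is the member mean,
and the uncertainty is the sample standard deviation over members scaled by a
calibration factor c, floored at the mean test-set RMSE of the members
(predictions tighter than the test error are not trustworthy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorConfig, featurize
from .system import AtomicSystem, RegionPartition, partition_regions

__all__ = [
    "NetworkSpec",
    "HDNNPModel",
    "EnsembleModel",
    "TrainingDataset",
    "Frame",
    "train_hdnnp",
    "predict_energy",
    "predict_forces",
    "ensemble_predict",
    "HDNNPEnsemble",
    "EnsembleFitResult",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one per-element subnetwork: two hidden layers, linear output."""

    n_input: int
    hidden: tuple[int, int]
    activation: str = "tanh"
    init_seed: int = 0

    def __post_init__(self):
        if len(self.hidden) != 2:
            raise ValueError("exactly two hidden layers")
        if self.activation != "tanh":
            raise ValueError("only the tanh activation is implemented")


def _init_params(spec: NetworkSpec) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(spec.init_seed)
    n_in, (h1, h2) = spec.n_input, spec.hidden
    return {
        "W1": rng.normal(0.0, 1.0 / np.sqrt(n_in), (h1, n_in)),
        "b1": np.zeros(h1),
        "W2": rng.normal(0.0, 1.0 / np.sqrt(h1), (h2, h1)),
        "b2": np.zeros(h2),
        "w3": rng.normal(0.0, 1.0 / np.sqrt(h2), h2),
        "b3": np.zeros(1),
    }


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """One training/test conformation with precomputed features.

    ``force_mask`` marks atoms carrying ML force targets (Q and E');
    ``jacobians`` is the list of per-center descriptor Jacobians.
    """

    features: np.ndarray            # (n_qm, n_features)
    jacobians: list                 # DescriptorJacobian per QM atom
    qm_elements: list[str]
    n_atoms: int
    e_target: float                 # kJ/mol
    f_target: np.ndarray            # (n_atoms, 3); zeros outside mask
    force_mask: np.ndarray          # (n_atoms,) bool
    frame_id: int = -1


class TrainingDataset:
    """Featurized frames with a deterministic train/test split by frame."""

    def __init__(self, frames: list[Frame], config: DescriptorConfig,
                 test_fraction: float = 0.1, split_seed: int = 0):
        if not frames:
            raise ValueError("empty dataset")
        self.frames = frames
        self.config = config
        rng = np.random.default_rng(split_seed)
        n = len(frames)
        order = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n))) if n > 1 else 0
        self.test_idx = np.sort(order[:n_test])
        self.train_idx = np.sort(order[n_test:])
        if self.train_idx.size == 0:
            raise ValueError("train split empty")

    def subset(self, idx) -> list[Frame]:
        return [self.frames[i] for i in idx]

    @property
    def elements(self) -> list[str]:
        out = set()
        for f in self.frames:
            out.update(f.qm_elements)
        return sorted(out)


class _Packed:
    """Flat arrays over (frame, center) rows for vectorized training."""

    def __init__(self, frames: list[Frame], elements: list[str],
                 jac_dtype=np.float32):
        nf = frames[0].features.shape[1]
        rows_x, rows_elem, rows_frame = [], [], []
        self.n_frames = len(frames)
        self.nq = np.array([f.features.shape[0] for f in frames])
        self.e_ref = np.array([f.e_target for f in frames])
        atom_offsets = np.concatenate([[0], np.cumsum([f.n_atoms for f in frames])])
        self.total_atoms = int(atom_offsets[-1])
        self.f_ref = np.concatenate([f.f_target for f in frames], axis=0)
        self.f_mask = np.concatenate([f.force_mask for f in frames])
        max_local = max(j.atom_indices.size for f in frames for j in f.jacobians)
        elem_ids = {e: i for i, e in enumerate(elements)}
        n_rows = int(self.nq.sum())
        self.X = np.empty((n_rows, nf))
        self.elem = np.empty(n_rows, dtype=int)
        self.frame = np.empty(n_rows, dtype=int)
        # padded Jacobians and a global scatter map (pad slots -> dump index)
        self.J = np.zeros((n_rows, nf, max_local, 3), dtype=jac_dtype)
        self.amap = np.full((n_rows, max_local), self.total_atoms, dtype=int)
        r = 0
        for fi, f in enumerate(frames):
            for ci in range(f.features.shape[0]):
                self.X[r] = f.features[ci]
                e = f.qm_elements[ci]
                if e not in elem_ids:
                    raise ValueError(f"element {e!r} unknown to the model")
                self.elem[r] = elem_ids[e]
                self.frame[r] = fi
                jac = f.jacobians[ci]
                nl = jac.atom_indices.size
                self.J[r, :, :nl, :] = jac.values
                self.amap[r, :nl] = atom_offsets[fi] + jac.atom_indices
                r += 1
        self.n_rows = n_rows
        self.n_features = nf
        self.J_flat = self.J.reshape(n_rows, nf, max_local * 3)
        self.max_local = max_local
        # number of supervised force components
        self.n_force_comp = max(1, 3 * int(self.f_mask.sum()))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class HDNNPModel:
    """Per-element subnetworks plus frozen standardization constants."""

    def __init__(self, elements: list[str], spec_hidden: tuple[int, int],
                 config: DescriptorConfig, init_seed: int = 0):
        self.elements = list(elements)
        self.hidden = tuple(spec_hidden)
        self.config = config
        self.init_seed = init_seed
        nf = config.n_features
        self.nets = {
            e: _init_params(NetworkSpec(nf, self.hidden,
                                        init_seed=init_seed * 1009 + k))
            for k, e in enumerate(self.elements)
        }
        self.x_mean = np.zeros(nf)
        self.x_std = np.ones(nf)
        self.y_mean = 0.0   # mean target energy per QM atom
        self.y_std = 1.0

    # -- standardization ----------------------------------------------
    def set_standardization(self, frames: list[Frame]):
        X = np.concatenate([f.features for f in frames], axis=0)
        self.x_mean = X.mean(axis=0)
        std = X.std(axis=0)
        self.x_std = np.where(std > 1e-10, std, 1.0)
        per_atom = np.array([f.e_target / f.features.shape[0] for f in frames])
        self.y_mean = float(per_atom.mean())
        self.y_std = float(per_atom.std()) or 1.0

    # -- core network evaluation --------------------------------------
    def _forward_rows(self, Xs: np.ndarray, elem_ids: np.ndarray,
                      need_input_grad: bool):
        """Standardized atomic energies (and d e_atom / d g-standardized)."""
        e_atom = np.empty(Xs.shape[0])
        s = np.empty_like(Xs) if need_input_grad else None
        cache = {}
        for k, e in enumerate(self.elements):
            rows = np.flatnonzero(elem_ids == k)
            if rows.size == 0:
                continue
            p = self.nets[e]
            g = Xs[rows]
            a1 = np.tanh(g @ p["W1"].T + p["b1"])
            a2 = np.tanh(a1 @ p["W2"].T + p["b2"])
            e_atom[rows] = a2 @ p["w3"] + p["b3"][0]
            cache[e] = (rows, g, a1, a2)
            if need_input_grad:
                t2 = (1.0 - a2 ** 2) * p["w3"]
                t1 = (t2 @ p["W2"]) * (1.0 - a1 ** 2)
                s[rows] = t1 @ p["W1"]
        return e_atom, s, cache

    def _energies_from_rows(self, e_atom, frame_ids, n_frames, nq):
        e_sum = np.zeros(n_frames)
        np.add.at(e_sum, frame_ids, e_atom)
        return self.y_mean * nq + self.y_std * e_sum

    # -- public prediction --------------------------------------------
    def predict_from_features(self, G: np.ndarray, qm_elements: list[str],
                              jacobians=None, n_atoms: int | None = None):
        """ML energy (and forces) from precomputed descriptors/Jacobians."""
        for e in qm_elements:
            if e not in self.nets:
                raise ValueError(f"element {e!r} unknown to model")
        Xs = (G - self.x_mean) / self.x_std
        elem_ids = np.array([self.elements.index(e) for e in qm_elements])
        with_forces = jacobians is not None
        e_atom, s, _ = self._forward_rows(Xs, elem_ids,
                                          need_input_grad=with_forces)
        energy = float(self.y_mean * len(qm_elements)
                       + self.y_std * e_atom.sum())
        if not with_forces:
            return energy, None
        f = np.zeros((n_atoms, 3))
        s_phys = self.y_std * s / self.x_std  # d E / d G (unstandardized)
        for r, jac in enumerate(jacobians):
            f[jac.atom_indices] -= np.einsum("i,ilx->lx", s_phys[r], jac.values)
        return energy, f

    def predict(self, system: AtomicSystem, partition: RegionPartition | None = None,
                forces: bool = True):
        """ML energy (kJ/mol) and, optionally, forces on Q and E' atoms."""
        if partition is None:
            partition = partition_regions(system, self.config.r_cut)
        qm_elements = [system.elements[i] for i in partition.Q]
        if forces:
            G, jacs = featurize(system, partition, self.config, gradients=True)
            return self.predict_from_features(G, qm_elements, jacs,
                                              system.n_atoms)
        G = featurize(system, partition, self.config)
        return self.predict_from_features(G, qm_elements)


def predict_energy(model: HDNNPModel, system: AtomicSystem,
                   partition: RegionPartition | None = None) -> float:
    return model.predict(system, partition, forces=False)[0]


def predict_forces(model: HDNNPModel, system: AtomicSystem,
                   partition: RegionPartition | None = None) -> np.ndarray:
    return model.predict(system, partition, forces=True)[1]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grad(model: HDNNPModel, pk: _Packed, w_e: float, w_f: float,
                   with_forces: bool):
    """Exact loss and parameter gradient on a packed dataset.

    Energy term: mean over frames of ((E_pred - E_ref)/n_Q)^2.
    Force term: mean over supervised components of (F_pred - F_ref)^2.
    """
    Xs = (pk.X - model.x_mean) / model.x_std
    e_atom, s_std, cache = model._forward_rows(Xs, pk.elem,
                                               need_input_grad=with_forces)
    e_pred = model._energies_from_rows(e_atom, pk.frame, pk.n_frames, pk.nq)
    de = (e_pred - pk.e_ref) / pk.nq
    loss_e = float(np.mean(de ** 2))
    # upstream scalar per row for the energy term (standardized units)
    c_frame = 2.0 * w_e * de / pk.nq / pk.n_frames * model.y_std
    c_row = c_frame[pk.frame]

    grads = {e: {k: np.zeros_like(v) for k, v in model.nets[e].items()}
             for e in model.elements}

    loss_f = 0.0
    f_pred = None
    if with_forces:
        scale = (model.y_std / model.x_std)
        s_phys = (s_std * scale).astype(pk.J.dtype)
        contrib = np.matmul(s_phys[:, None, :], pk.J_flat)[:, 0, :]
        f_pred = np.zeros((pk.total_atoms + 1, 3))
        np.add.at(f_pred, pk.amap.reshape(-1),
                  -contrib.reshape(-1, 3).astype(float))
        f_pred = f_pred[:-1]
        resid = (f_pred - pk.f_ref) * pk.f_mask[:, None]
        loss_f = float(np.sum(resid ** 2) / pk.n_force_comp)
        # dL/ds_phys via the same contraction, transposed
        up = np.concatenate([2.0 * w_f * resid / pk.n_force_comp,
                             np.zeros((1, 3))], axis=0)
        r_loc = up[pk.amap].astype(pk.J.dtype)          # (R, L, 3)
        u = -np.matmul(pk.J_flat,
                       r_loc.reshape(pk.n_rows, -1, 1))[:, :, 0].astype(float)
        u_hat = u * scale  # tangent direction in standardized input space

    for e in model.elements:
        if e not in cache:
            continue
        rows, g, a1, a2 = cache[e]
        p = model.nets[e]
        gr = grads[e]
        c = c_row[rows]
        # --- energy part: plain backprop with upstream c ---
        gr["w3"] += c @ a2
        gr["b3"][0] += c.sum()
        dz2 = c[:, None] * p["w3"] * (1.0 - a2 ** 2)
        gr["W2"] += dz2.T @ a1
        gr["b2"] += dz2.sum(axis=0)
        dz1 = (dz2 @ p["W2"]) * (1.0 - a1 ** 2)
        gr["W1"] += dz1.T @ g
        gr["b1"] += dz1.sum(axis=0)
        if not with_forces:
            continue
        # --- force part: grad of sum_r u_r . dE/dg_r (forward-over-reverse) ---
        uh = u_hat[rows]
        z1d = uh @ p["W1"].T
        a1d = (1.0 - a1 ** 2) * z1d
        z2d = a1d @ p["W2"].T
        a2d = (1.0 - a2 ** 2) * z2d
        d2 = (1.0 - a2 ** 2) * p["w3"]          # delta2 with unit upstream
        d2d = p["w3"] * (-2.0 * a2 * a2d)
        gr["w3"] += a2d.sum(axis=0)
        gr["W2"] += d2d.T @ a1 + d2.T @ a1d
        gr["b2"] += d2d.sum(axis=0)
        d1 = (d2 @ p["W2"]) * (1.0 - a1 ** 2)
        d1d = (d2d @ p["W2"]) * (1.0 - a1 ** 2) + (d2 @ p["W2"]) * (-2.0 * a1 * a1d)
        gr["W1"] += d1d.T @ g + d1.T @ uh
        gr["b1"] += d1d.sum(axis=0)

    loss = w_e * loss_e + w_f * loss_f
    return loss, loss_e, loss_f, grads, e_pred, f_pred


class _Adam:
    def __init__(self, model: HDNNPModel, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {e: {k: np.zeros_like(v) for k, v in model.nets[e].items()}
                  for e in model.elements}
        self.v = {e: {k: np.zeros_like(v) for k, v in model.nets[e].items()}
                  for e in model.elements}

    def step(self, model: HDNNPModel, grads):
        self.t += 1
        corr1 = 1.0 - self.b1 ** self.t
        corr2 = 1.0 - self.b2 ** self.t
        for e in model.elements:
            for k, p in model.nets[e].items():
                g = grads[e][k]
                m = self.m[e][k] = self.b1 * self.m[e][k] + (1 - self.b1) * g
                v = self.v[e][k] = self.b2 * self.v[e][k] + (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


@dataclass
class TrainResult:
    model: HDNNPModel
    loss_trace: np.ndarray          # (epochs, 3): total, energy, force terms
    rmse_energy_train: float        # kJ/mol per QM atom
    rmse_energy_test: float
    rmse_force_train: float         # kJ/mol/Å over supervised components
    rmse_force_test: float
    mean_n_qm: float = 1.0          # converts per-atom to total-energy RMSE

    @property
    def rmse_energy_test_total(self) -> float:
        """Test RMSE on the total-energy scale (floor for Eq-20 uncertainty)."""
        return self.rmse_energy_test * self.mean_n_qm


def _rmses(model, frames, jac_dtype=np.float32):
    if not frames:
        return np.nan, np.nan
    pk = _Packed(frames, model.elements, jac_dtype=jac_dtype)
    _, le, lf, _, e_pred, f_pred = _loss_and_grad(model, pk, 1.0, 1.0, True)
    return float(np.sqrt(le)), float(np.sqrt(lf))


def train_hdnnp(model: HDNNPModel, dataset: TrainingDataset,
                epochs: int = 1000, loss_weights: tuple[float, float] = (1.0, 0.1),
                seed: int = 0, lr: float = 1e-2, lr_decay: float = 0.999,
                jac_dtype=np.float32) -> TrainResult:
    """Fit one HDNNP by full-batch Adam; deterministic given the seed.

    ``loss_weights = (w_E, w_F)`` balance the per-QM-atom energy MSE against
    the per-component force MSE over Q and E'. The learning rate decays
    geometrically by ``lr_decay`` per epoch.
    """
    w_e, w_f = loss_weights
    train = dataset.subset(dataset.train_idx)
    test = dataset.subset(dataset.test_idx)
    model.set_standardization(train)
    pk = _Packed(train, model.elements, jac_dtype=jac_dtype)
    opt = _Adam(model, lr)
    trace = np.empty((epochs, 3))
    with_forces = w_f > 0.0
    for ep in range(epochs):
        opt.lr = lr * lr_decay ** ep
        loss, le, lf, grads, _, _ = _loss_and_grad(model, pk, w_e, w_f,
                                                   with_forces)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {ep}; trace:\n{trace[:ep]}")
        opt.step(model, grads)
        trace[ep] = (loss, le, lf)
    etr, ftr = _rmses(model, train, jac_dtype)
    ete, fte = _rmses(model, test, jac_dtype)
    mean_nq = float(np.mean([f.features.shape[0] for f in (test or train)]))
    return TrainResult(model, trace, etr, ete, ftr, fte, mean_nq)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

class EnsembleModel:
    """Committee of HDNNPs with an RMSE-floored spread uncertainty."""

    def __init__(self, members: list[HDNNPModel], rmse_floor_energy: float = 0.0,
                 rmse_floor_force: float = 0.0, c: float = 1.0):
        if len(members) < 2:
            raise ValueError("an ensemble needs at least two members")
        if rmse_floor_energy < 0 or rmse_floor_force < 0:
            raise ValueError("RMSE floors must be non-negative")
        self.members = members
        self.rmse_floor_energy = rmse_floor_energy
        self.rmse_floor_force = rmse_floor_force
        self.c = c

    @property
    def config(self) -> DescriptorConfig:
        return self.members[0].config

    def predict(self, system: AtomicSystem,
                partition: RegionPartition | None = None, forces: bool = True):
        """(mean energy, energy uncertainty, mean forces, force uncertainties)."""
        if partition is None:
            partition = partition_regions(system, self.config.r_cut)
        qm_elements = [system.elements[i] for i in partition.Q]
        if forces:  # featurize once, share across members
            G, jacs = featurize(system, partition, self.config, gradients=True)
        else:
            G, jacs = featurize(system, partition, self.config), None
        n = len(self.members)
        energies = np.empty(n)
        fstack = None
        for p, m in enumerate(self.members):
            e, f = m.predict_from_features(G, qm_elements, jacs,
                                           system.n_atoms)
            energies[p] = e
            if forces:
                if fstack is None:
                    fstack = np.empty((n,) + f.shape)
                fstack[p] = f
        e_mean = float(energies.mean())
        spread = np.sqrt(self.c ** 2 / (n - 1)
                         * np.sum((energies - e_mean) ** 2))
        de = max(self.rmse_floor_energy, float(spread))
        if not forces:
            return e_mean, de, None, None
        f_mean = fstack.mean(axis=0)
        f_spread = np.sqrt(self.c ** 2 / (n - 1)
                           * np.sum((fstack - f_mean) ** 2, axis=0))
        df = np.maximum(self.rmse_floor_force, f_spread)
        return e_mean, de, f_mean, df


def ensemble_predict(ensemble: EnsembleModel, system: AtomicSystem,
                     partition: RegionPartition | None = None):
    return ensemble.predict(system, partition)


@dataclass
class EnsembleFitResult:
    """Fit summary of an HDNNP committee."""

    ensemble: EnsembleModel
    member_results: list[TrainResult]

    @property
    def rmse_energy_test(self) -> np.ndarray:
        return np.array([r.rmse_energy_test for r in self.member_results])

    @property
    def rmse_force_test(self) -> np.ndarray:
        return np.array([r.rmse_force_test for r in self.member_results])

    def ensemble_rmse(self, dataset: TrainingDataset):
        """Test RMSEs of the committee-mean prediction (energy per QM atom, force)."""
        frames = dataset.subset(dataset.test_idx)
        members = self.ensemble.members
        pk = _Packed(frames, members[0].elements)
        e_stack, f_stack = [], []
        for m in members:
            _, _, _, _, e_pred, f_pred = _loss_and_grad(m, pk, 1.0, 1.0, True)
            e_stack.append(e_pred)
            f_stack.append(f_pred)
        e_mean = np.mean(e_stack, axis=0)
        f_mean = np.mean(f_stack, axis=0)
        e_rmse = float(np.sqrt(np.mean(((e_mean - pk.e_ref) / pk.nq) ** 2)))
        resid = (f_mean - pk.f_ref) * pk.f_mask[:, None]
        f_rmse = float(np.sqrt(np.sum(resid ** 2) / pk.n_force_comp))
        return e_rmse, f_rmse

    def summary(self) -> str:
        lines = ["HDNNP ensemble fit",
                 "=" * 46,
                 f"members: {len(self.member_results)}",
                 f"{'member':>6} {'E test RMSE':>14} {'F test RMSE':>14}"]
        for i, r in enumerate(self.member_results):
            lines.append(f"{i:>6} {r.rmse_energy_test:>14.4f} "
                         f"{r.rmse_force_test:>14.4f}")
        lines.append("-" * 46)
        lines.append(f"energy RMSE floor: {self.ensemble.rmse_floor_energy:.4f} "
                     "kJ/mol (total energy)")
        lines.append(f"force RMSE floor:  {self.ensemble.rmse_floor_force:.4f} "
                     "kJ/mol/Å")
        return "\n".join(lines)


class HDNNPEnsemble:
    """Model object for fitting a committee of HDNNPs to a featurized dataset.

    Parameters
    ----------
    dataset : TrainingDataset
    hidden : (int, int), optional
        Hidden-layer widths; defaults to twice the square root of the
        descriptor length, rounded.
    n_members : int
        Committee size (>= 2).
    c : float
        Uncertainty calibration factor.
    """

    def __init__(self, dataset: TrainingDataset, hidden=None, n_members: int = 10,
                 c: float = 1.0):
        self.dataset = dataset
        nf = dataset.config.n_features
        if hidden is None:
            h = max(4, int(round(2 * np.sqrt(nf))))
            hidden = (h, h)
        self.hidden = tuple(hidden)
        self.n_members = n_members
        self.c = c

    def fit(self, epochs: int = 1000, seed: int = 0,
            loss_weights: tuple[float, float] = (1.0, 0.1),
            lr: float = 1e-2, lr_decay: float = 0.999) -> EnsembleFitResult:
        elements = self.dataset.elements
        results = []
        for p in range(self.n_members):
            model = HDNNPModel(elements, self.hidden, self.dataset.config,
                               init_seed=seed * 7919 + p)
            results.append(train_hdnnp(model, self.dataset, epochs=epochs,
                                       loss_weights=loss_weights,
                                       seed=seed * 7919 + p, lr=lr,
                                       lr_decay=lr_decay))
        # floors live on the scales the uncertainties are compared on:
        # total energy (kJ/mol) and force components (kJ/mol/Å)
        floor_e = float(np.mean([r.rmse_energy_test_total for r in results]))
        floor_f = float(np.mean([r.rmse_force_test for r in results]))
        ens = EnsembleModel([r.model for r in results], floor_e, floor_f, self.c)
        return EnsembleFitResult(ens, results)
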