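"""Element-embracing atom-centered symmetry functions with QM/MM channels.

Each QM atom gets a fixed-length, rotation/translation/permutation-invariant
feature vector describing its local environment within a cutoff ``r_cut``.
Element identity enters through seven periodic-table property channels
(constant, period ``n``, main-group ``m``, d-column ``d`` and their reversed
counterparts) normalized to [0, 1], so the vector length is independent of
how many chemical elements occur — unlike classic per-element ACSFs whose
angular block grows with the number of unordered element pairs.

In QM/MM mode, interaction masks split every block by neighbor region
(QM-only, MM-only, and mixed angular triples), and MM neighbors — whose only
attribute besides position is their point charge — contribute through
charge-weighted channels instead of element channels.

Radial block, feature i of center n:    G_i = sum_j I_ij * H_ij * F_rad(R_nj)
Angular block, over unordered pairs:    G_i = sum_{j<k} I_ijk * H_ijk
                                              * F_ang(theta_njk)
                                              * F_rad(R_nj) * F_rad(R_nk)

``F_rad(r) = exp(eta * (1 - (1 - r^2/r_cut^2)^-1))`` for ``r < r_cut`` and 0
beyond: it takes the role of a cutoff function as well, damping the value and
all derivatives smoothly to zero at ``r_cut``.
``F_ang(theta) = (1/2 + lambda/2 * cos(theta))^zeta``.

Analytic position gradients (Jacobians) are provided for force prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import CHANNEL_MAX, CHANNEL_NAMES, element_properties
from .system import QM, AtomicSystem, RegionPartition

__all__ = [
    "DescriptorConfig",
    "DescriptorVector",
    "DescriptorJacobian",
    "radial_structure",
    "radial_structure_derivative",
    "angular_structure",
    "radial_element_weight",
    "angular_element_weight",
    "radial_charge_weight",
    "angular_mixed_weight",
    "angular_charge_weight",
    "interaction_mask",
    "compute_descriptors",
    "compute_jacobian",
    "featurize",
    "descriptor_size",
]

# Angular element-channel plan: all seven channels as sums (gamma=+1) plus
# the first four as differences (gamma=-1) -> 11 channels per
# (eta_ang, lambda, zeta) combination.
_ANGULAR_GAMMA_PLAN: tuple[tuple[int, int], ...] = tuple(
    [(c, +1) for c in range(7)] + [(c, -1) for c in range(4)]
)


@dataclass(frozen=True)
class DescriptorConfig:
    """Hyperparameters of the descriptor.

    ``eta_rad`` / ``eta_ang`` are dimensionless decay parameters of the radial
    structure function (the radial distance enters scaled by ``r_cut``);
    ``lambda_vals`` (±1) and ``zeta_vals`` (>= 1) shape the angular function;
    ``q_max`` is the maximal absolute MM point charge used to normalize the
    charge channels. ``qmmm_mode`` enables the region-mask and charge channels.
    """

    eta_rad: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    eta_ang: tuple[float, ...] = (1.0, 4.0)
    lambda_vals: tuple[int, ...] = (1, -1)
    zeta_vals: tuple[float, ...] = (1.0, 4.0, 16.0)
    r_cut: float = 5.0
    q_max: float = 1.0
    qmmm_mode: bool = True

    def __post_init__(self):
        if not all(e > 0 for e in self.eta_rad + self.eta_ang):
            raise ValueError("all eta must be positive")
        if not all(l in (1, -1) for l in self.lambda_vals):
            raise ValueError("lambda values must be +1 or -1")
        if not all(z >= 1 for z in self.zeta_vals):
            raise ValueError("zeta values must be >= 1")
        if self.r_cut <= 0 or self.q_max <= 0:
            raise ValueError("r_cut and q_max must be positive")

    @property
    def angular_combos(self) -> list[tuple[float, int, float]]:
        """(eta_ang, lambda, zeta) combinations in canonical order."""
        return [(e, l, z) for e in self.eta_ang for l in self.lambda_vals
                for z in self.zeta_vals]

    @property
    def n_radial(self) -> int:
        per_eta = 8 if self.qmmm_mode else 7
        return len(self.eta_rad) * per_eta

    @property
    def n_angular(self) -> int:
        per_combo = (len(_ANGULAR_GAMMA_PLAN) + 7 + 1) if self.qmmm_mode \
            else len(_ANGULAR_GAMMA_PLAN)
        return len(self.angular_combos) * per_combo

    @property
    def n_features(self) -> int:
        return self.n_radial + self.n_angular

    def feature_names(self) -> list[str]:
        names = []
        for eta in self.eta_rad:
            for c in range(7):
                tag = f"rad|eta={eta:g}|h={CHANNEL_NAMES[c]}"
                names.append(tag + "|QQ" if self.qmmm_mode else tag)
            if self.qmmm_mode:
                names.append(f"rad|eta={eta:g}|charge|QE")
        for eta, lam, zeta in self.angular_combos:
            combo = f"eta={eta:g}|lam={lam:+d}|zeta={zeta:g}"
            for c, gamma in _ANGULAR_GAMMA_PLAN:
                tag = f"ang|{combo}|h={CHANNEL_NAMES[c]}|gamma={gamma:+d}"
                names.append(tag + "|QQ" if self.qmmm_mode else tag)
            if self.qmmm_mode:
                names += [f"ang|{combo}|h={CHANNEL_NAMES[c]}xcharge|QE"
                          for c in range(7)]
                names.append(f"ang|{combo}|chargexcharge|EE")
        return names


@dataclass(frozen=True)
class DescriptorVector:
    center: int
    values: np.ndarray


@dataclass(frozen=True)
class DescriptorJacobian:
    """Sparse per-center Jacobian d G_i / d R_a.

    ``atom_indices`` lists the global indices of atoms with nonzero gradient
    (the center and its in-cutoff neighbors); ``values[i, a, :]`` is the
    gradient of feature ``i`` with respect to ``atom_indices[a]``.
    """

    center: int
    atom_indices: np.ndarray
    values: np.ndarray  # (n_features, n_local, 3)

    def entry(self, feature: int, atom: int) -> np.ndarray:
        loc = np.flatnonzero(self.atom_indices == atom)
        if loc.size == 0:
            return np.zeros(3)
        return self.values[feature, loc[0]]

    def entries(self) -> dict[tuple[int, int], np.ndarray]:
        out = {}
        for i in range(self.values.shape[0]):
            for a, idx in enumerate(self.atom_indices):
                g = self.values[i, a]
                if np.any(g != 0.0):
                    out[(i, int(idx))] = g
        return out


# ---------------------------------------------------------------------------
# elementary building blocks
# ---------------------------------------------------------------------------

def radial_structure(r, eta, r_cut):
    """Smoothly vanishing radial function; doubles as the cutoff function."""
    r = np.asarray(r, dtype=float)
    inside = r < r_cut
    u = np.where(inside, 1.0 - (r / r_cut) ** 2, 1.0)
    with np.errstate(over="ignore"):
        f = np.where(inside, np.exp(eta * (1.0 - 1.0 / u)), 0.0)
    return f if f.ndim else float(f)


def radial_structure_derivative(r, eta, r_cut):
    """d F_rad / d r (zero at and beyond the cutoff, continuously)."""
    r = np.asarray(r, dtype=float)
    inside = r < r_cut
    u = np.where(inside, 1.0 - (r / r_cut) ** 2, 1.0)
    f = np.where(inside, np.exp(eta * (1.0 - 1.0 / u)), 0.0)
    d = np.where(inside, -2.0 * eta * r / (r_cut ** 2 * u ** 2) * f, 0.0)
    return d if d.ndim else float(d)


def angular_structure(theta, lam, zeta):
    """Conventional angular function, in [0, 1] for theta in [0, pi]."""
    return (0.5 + 0.5 * lam * np.cos(theta)) ** zeta


def radial_element_weight(h, h_max):
    """Normalized element channel of a QM neighbor, in [0, 1]."""
    return h / h_max


def angular_element_weight(h_j, h_k, gamma, h_max):
    """Symmetric two-neighbor element weight.

    Sums (gamma=+1) are normalized by 2*h_max; absolute differences
    (gamma=-1) are shifted by one — unless both properties vanish — and
    normalized by h_max, so every pair contributes.
    """
    h_j = np.asarray(h_j, dtype=float)
    h_k = np.asarray(h_k, dtype=float)
    c = np.where((h_j == 0.0) & (h_k == 0.0), 0.0, 1.0)
    num = np.abs(h_j + gamma * h_k) + 0.5 * (1 - gamma) * c
    den = h_max * (0.5 * (1 + gamma) + 1.0)
    out = num / den
    return out if out.ndim else float(out)


def radial_charge_weight(q, q_max):
    """Charge channel of an MM neighbor, in [-1/2, 1/2] for |q| <= q_max."""
    return q / (2.0 * q_max)


def angular_mixed_weight(h_qm, q_mm, h_max, q_max):
    """Mixed QM-element x MM-charge angular weight (slot-symmetric)."""
    return h_qm * q_mm / (2.0 * h_max * q_max)


def angular_charge_weight(q_j, q_k, q_max):
    """Charge x charge angular weight for two MM neighbors."""
    return q_j * q_k / (2.0 * q_max ** 2)


def interaction_mask(kind: str, regions) -> float:
    """Region selector t^Q / t^E products.

    ``kind`` is ``"radial_Q"``/``"radial_E"`` with one neighbor region, or
    ``"angular_QQ"``/``"angular_QE"``/``"angular_EE"`` with a pair of regions
    (order-independent for the mixed channel).
    """
    if kind.startswith("radial"):
        region = regions if isinstance(regions, str) else regions[0]
        want = QM if kind.endswith("Q") else "MM"
        return 1.0 if region == want else 0.0
    rj, rk = regions
    tq = (rj == QM, rk == QM)
    if kind == "angular_QQ":
        return 1.0 if tq == (True, True) else 0.0
    if kind == "angular_EE":
        return 1.0 if tq == (False, False) else 0.0
    if kind == "angular_QE":
        return 1.0 if tq[0] != tq[1] else 0.0
    raise ValueError(f"unknown mask kind {kind!r}")


# ---------------------------------------------------------------------------
# full descriptor evaluation
# ---------------------------------------------------------------------------

_CHANNEL_MAX_ARR = np.asarray(CHANNEL_MAX)


def _frad_batch(r: np.ndarray, etas: np.ndarray, r_cut: float,
                with_deriv: bool):
    """Radial structure values (n_eta, n) and optionally derivatives."""
    inside = r < r_cut
    u = np.where(inside, 1.0 - (r / r_cut) ** 2, 1.0)
    expo = (1.0 - 1.0 / u)[None, :] * etas[:, None]
    f = np.exp(expo) * inside[None, :]
    if not with_deriv:
        return f, None
    df = f * (-2.0 / r_cut ** 2) * (etas[:, None] * (r / u ** 2)[None, :])
    return f, df
_ELEMENT_CHANNEL_CACHE: dict[str, np.ndarray] = {}


def _element_channels_normalized(symbol: str) -> np.ndarray:
    out = _ELEMENT_CHANNEL_CACHE.get(symbol)
    if out is None:
        out = np.asarray(element_properties(symbol).channels) / _CHANNEL_MAX_ARR
        _ELEMENT_CHANNEL_CACHE[symbol] = out
    return out


def _neighbor_data(system, partition, config, center):
    """Neighbors of one QM center: QM atoms and E' MM atoms within r_cut."""
    cand = np.concatenate([partition.Q[partition.Q != center], partition.E_prime])
    cand = cand.astype(int)
    d = system.positions[cand] - system.positions[center]
    r = np.linalg.norm(d, axis=1)
    keep = r < config.r_cut
    cand, d, r = cand[keep], d[keep], r[keep]
    is_qm = (system.regions[cand] == QM).astype(float)
    # 7 x nn matrix of normalized element channels; in QM/MM mode the element
    # identity of MM neighbors is invisible (only their charge enters)
    hmat = np.zeros((7, cand.size))
    for a, idx in enumerate(cand):
        if is_qm[a] or not config.qmmm_mode:
            hmat[:, a] = _element_channels_normalized(system.elements[idx])
    qnorm = system.charges[cand] / (2.0 * config.q_max) * (1.0 - is_qm)
    return cand, d, r, is_qm, hmat, qnorm


def _raw_hmat(system, cand):
    """Unnormalized 7 x nn element-channel matrix (all neighbors)."""
    hmat = np.zeros((7, len(cand)))
    for a, idx in enumerate(cand):
        hmat[:, a] = element_properties(system.elements[idx]).channels
    return hmat


def _radial_weight_matrix(config, is_qm, hmat, qnorm):
    """Per-eta channel-weight matrix W[c, j] = I * H (eta-independent part)."""
    if config.qmmm_mode:
        w = np.vstack([hmat * is_qm[None, :], (qnorm * (1.0 - is_qm))[None, :]])
    else:
        w = hmat
    return w


def _angular_weight_matrix(config, is_qm, hmat_raw, qnorm):
    """Channel-weight matrix over neighbor pairs, one row per angular channel.

    Returns (W, jdx, kdx): W is (n_channels_per_combo, n_pairs); the channel
    weights do not depend on (eta_ang, lambda, zeta), so one matrix serves all
    combinations.
    """
    nn = is_qm.size
    jdx, kdx = np.triu_indices(nn, k=1)
    hmax = _CHANNEL_MAX_ARR
    if config.qmmm_mode:
        mask_qq = is_qm[jdx] * is_qm[kdx]
        mask_ee = (1 - is_qm[jdx]) * (1 - is_qm[kdx])
    else:
        mask_qq = np.ones(jdx.size)
    hj, hk = hmat_raw[:, jdx], hmat_raw[:, kdx]       # (7, P)
    w_sum = np.abs(hj + hk) / (2.0 * hmax[:, None])   # gamma = +1, 7 channels
    c4 = ((hj[:4] != 0.0) | (hk[:4] != 0.0)).astype(float)
    w_diff = (np.abs(hj[:4] - hk[:4]) + c4) / hmax[:4, None]  # gamma = -1
    rows = [w_sum * mask_qq, w_diff * mask_qq]
    if config.qmmm_mode:
        hn = hmat_raw / hmax[:, None]  # normalized element channels
        w_mixed = (is_qm[jdx] * (1 - is_qm[kdx]) * hn[:, jdx] * qnorm[kdx]
                   + (1 - is_qm[jdx]) * is_qm[kdx] * hn[:, kdx] * qnorm[jdx])
        rows.append(w_mixed)
        # qnorm = q/(2 q_max) so 2*qn_j*qn_k = q_j q_k / (2 q_max^2)
        rows.append((mask_ee * 2.0 * qnorm[jdx] * qnorm[kdx])[None, :])
    return np.concatenate(rows, axis=0), jdx, kdx


def _center_descriptor(system, partition, config, center, with_grad):
    cand, d, r, is_qm, hmat_n, qnorm = _neighbor_data(
        system, partition, config, center)
    nf = config.n_features
    values = np.zeros(nf)
    nn = cand.size
    if with_grad:
        local = np.concatenate([[center], cand]).astype(int)
        jac = np.zeros((nf, nn + 1, 3))
    if nn == 0:
        if with_grad:
            return values, DescriptorJacobian(center, np.array([center]),
                                              np.zeros((nf, 1, 3)))
        return values

    hmat_raw = hmat_n * _CHANNEL_MAX_ARR[:, None]
    u = d / r[:, None]  # unit vectors center -> neighbor

    # ----- radial block -----
    wrad = _radial_weight_matrix(config, is_qm, hmat_n, qnorm)
    per_eta = wrad.shape[0]
    pos = 0
    fr, dfr = _frad_batch(r, np.asarray(config.eta_rad), config.r_cut,
                          with_grad)
    n_eta = len(config.eta_rad)
    values[:n_eta * per_eta] = (fr @ wrad.T).reshape(-1)
    if with_grad:
        g = (wrad[None, :, :, None]
             * (dfr[:, None, :, None] * u[None, None, :, :]))  # (e, c, nn, 3)
        g = g.reshape(n_eta * per_eta, nn, 3)
        jac[:n_eta * per_eta, 1:, :] += g
        jac[:n_eta * per_eta, 0, :] -= g.sum(axis=1)
    pos = n_eta * per_eta

    # ----- angular block -----
    if nn >= 2:
        wang, jdx, kdx = _angular_weight_matrix(config, is_qm, hmat_raw, qnorm)
        per_combo = wang.shape[0]
        rj, rk = r[jdx], r[kdx]
        dj, dk = d[jdx], d[kdx]
        cosq = np.einsum("px,px->p", dj, dk) / (rj * rk)
        cosq = np.clip(cosq, -1.0, 1.0)
        # radial pair factors per distinct eta_ang, reused across combos
        etas_ang = np.asarray(config.eta_ang)
        fj_all, dfj_all = _frad_batch(rj, etas_ang, config.r_cut, with_grad)
        fk_all, dfk_all = _frad_batch(rk, etas_ang, config.r_cut, with_grad)
        eta_pos = {eta: i for i, eta in enumerate(config.eta_ang)}
        if with_grad:
            gcos_j = dk / (rj * rk)[:, None] - (cosq / rj ** 2)[:, None] * dj
            gcos_k = dj / (rj * rk)[:, None] - (cosq / rk ** 2)[:, None] * dk
            gj_all = np.empty((len(config.angular_combos), jdx.size, 3))
            gk_all = np.empty_like(gj_all)
        for ci, (eta, lam, zeta) in enumerate(config.angular_combos):
            ei = eta_pos[eta]
            fj, fk = fj_all[ei], fk_all[ei]
            a = 0.5 + 0.5 * lam * cosq
            fa = a ** zeta
            values[pos + ci * per_combo:pos + (ci + 1) * per_combo] = \
                wang @ (fa * fj * fk)
            if with_grad:
                if zeta == 1.0:
                    dfa = np.full_like(a, 0.5 * lam)
                else:
                    dfa = zeta * 0.5 * lam * a ** (zeta - 1.0)
                ang_part = dfa * fj * fk
                gj_all[ci] = (ang_part[:, None] * gcos_j
                              + (fa * dfj_all[ei] * fk)[:, None] * u[jdx])
                gk_all[ci] = (ang_part[:, None] * gcos_k
                              + (fa * fj * dfk_all[ei])[:, None] * u[kdx])
        n_combo = len(config.angular_combos)
        if with_grad:
            # scatter channel-weighted pair gradients onto neighbor slots
            # via incidence matmuls: (K*C*3, P) @ (P, nn)
            P = jdx.size
            sj = np.zeros((P, nn))
            sj[np.arange(P), jdx] = 1.0
            sk = np.zeros((P, nn))
            sk[np.arange(P), kdx] = 1.0
            mj = (wang[None, :, :, None] * gj_all[:, None, :, :])  # (K,C,P,3)
            mk = (wang[None, :, :, None] * gk_all[:, None, :, :])
            mj = mj.transpose(0, 1, 3, 2).reshape(-1, P)
            mk = mk.transpose(0, 1, 3, 2).reshape(-1, P)
            block = (mj @ sj + mk @ sk).reshape(n_combo, per_combo, 3, nn)
            block = block.transpose(0, 1, 3, 2).reshape(
                n_combo * per_combo, nn, 3)
            jac[pos:pos + n_combo * per_combo, 1:, :] += block
            jac[pos:pos + n_combo * per_combo, 0, :] -= block.sum(axis=1)
        pos += n_combo * per_combo

    if with_grad:
        return values, DescriptorJacobian(center, local, jac)
    return values


def _check_partition(system, partition):
    if not np.array_equal(np.sort(partition.Q), system.qm_indices):
        raise ValueError("partition inconsistent with system QM region")


def compute_descriptors(system: AtomicSystem, partition: RegionPartition,
                        config: DescriptorConfig) -> list[DescriptorVector]:
    """One descriptor vector per QM atom."""
    _check_partition(system, partition)
    return [DescriptorVector(int(c), _center_descriptor(system, partition,
                                                        config, int(c), False))
            for c in partition.Q]


def compute_jacobian(system: AtomicSystem, partition: RegionPartition,
                     config: DescriptorConfig) -> list[DescriptorJacobian]:
    """Analytic position gradients of every QM atom's descriptor vector."""
    _check_partition(system, partition)
    return [_center_descriptor(system, partition, config, int(c), True)[1]
            for c in partition.Q]


def featurize(system: AtomicSystem, partition: RegionPartition,
              config: DescriptorConfig, gradients: bool = False):
    """Descriptor matrix (n_qm, n_features) and, optionally, Jacobians."""
    _check_partition(system, partition)
    if not gradients:
        g = np.array([_center_descriptor(system, partition, config, int(c), False)
                      for c in partition.Q])
        return g.reshape(len(partition.Q), config.n_features)
    vals, jacs = [], []
    for c in partition.Q:
        v, j = _center_descriptor(system, partition, config, int(c), True)
        vals.append(v)
        jacs.append(j)
    return np.array(vals), jacs


def descriptor_size(config: DescriptorConfig, n_elements: int = 1,
                    mode: str = "eeacsf_qmmm") -> tuple[int, int, int]:
    """Component counts (n_radial, n_angular, n_total) of a descriptor plan.

    ``acsf``: classic per-element radial channels and per-unordered-element-
    pair angular channels — grows with ``n_elements``. ``eeacsf``: the seven
    element-property channels with the package's gamma plan — element-count
    independent. ``eeacsf_qmmm`` additionally carries the region-mask and
    charge channels.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    n_combos = len(config.angular_combos)
    if mode == "acsf":
        n_rad = len(config.eta_rad) * n_elements
        n_ang = n_combos * (n_elements * (n_elements + 1) // 2)
    elif mode == "eeacsf":
        n_rad = len(config.eta_rad) * 7
        n_ang = n_combos * len(_ANGULAR_GAMMA_PLAN)
    elif mode == "eeacsf_qmmm":
        n_rad = len(config.eta_rad) * 8
        n_ang = n_combos * (len(_ANGULAR_GAMMA_PLAN) + 7 + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return n_rad, n_ang, n_rad + n_ang
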