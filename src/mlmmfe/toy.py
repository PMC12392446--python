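"""Toy host-ligand-solvent systems with an analytic reference oracle.

This module stands in for the QM/MM engine: a minimal MM force field
(harmonic bonds and angles, Lennard-Jones, Coulomb with 1-2/1-3 exclusions),
and an analytic oracle for the "QM + electrostatic embedding" energy of the
ligand. The oracle energy is

    E_oracle = E_intra-Q(perturbed) + E_Coul(Q<->E) + E_pol,
    E_pol    = kappa * k_e * sum_{I in Q} sum_{A in E} q_I q_A exp(-r_IA/r_pol),

where the intra-ligand bonded force constants are perturbed relative to the
MM ones (emulating an imperfect force field, so that the MM -> ML/MM
end-state correction is nonzero), and the short-ranged polarization term
E_pol emulates the response of the ligand's charge distribution to nearby
environment charges. Because the oracle contains the *exact* point-charge
Coulomb sum between the regions, subtracting it leaves a learning target
that is strictly short-ranged — the property that justifies a local
descriptor: a distant MM atom's influence decays like exp(-r/r_pol).

Harmonic convention: E = 1/2 k (r - r0)^2 and 1/2 k (theta - theta0)^2.
Lorentz-Berthelot combining rules for LJ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_CONSTANT
from .elements import ATOMIC_MASSES
from .system import (AtomicSystem, RegionPartition, coulomb_qm_mm,
                     partition_regions)

__all__ = [
    "ToyTopology",
    "OracleParams",
    "ReferenceRecord",
    "ToyForceField",
    "toy_mm_energy_forces",
    "toy_qm_oracle",
    "build_ml_target",
    "generate_fixtures",
]


@dataclass
class ToyTopology:
    """Bonded terms, LJ parameters, charges, and group labels."""

    bonds: np.ndarray          # (nb, 2) int
    bond_k: np.ndarray         # kJ/mol/Å^2
    bond_r0: np.ndarray        # Å
    angles: np.ndarray         # (na, 3) int, middle atom is the vertex
    angle_k: np.ndarray        # kJ/mol/rad^2
    angle_theta0: np.ndarray   # rad
    lj_eps: np.ndarray         # (n,), kJ/mol
    lj_sigma: np.ndarray       # (n,), Å
    charges: np.ndarray        # (n,), e
    groups: np.ndarray         # (n,) str: ligand | host | solvent

    def __post_init__(self):
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=int).reshape(-1, 3)
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "lj_eps", "lj_sigma", "charges"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.groups = np.asarray(self.groups, dtype=object)
        n = self.charges.size
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise ValueError("bond index out of range")
        if self.angles.size and (self.angles.min() < 0 or self.angles.max() >= n):
            raise ValueError("angle index out of range")
        if np.any(self.lj_eps <= 0) or np.any(self.lj_sigma <= 0):
            raise ValueError("LJ parameters must be positive")

    @property
    def n_atoms(self) -> int:
        return self.charges.size

    def exclusions(self) -> set[tuple[int, int]]:
        """1-2 and 1-3 pairs (bonded and angle-terminal), as sorted tuples."""
        excl = {tuple(sorted(b)) for b in self.bonds.tolist()}
        excl |= {tuple(sorted((a[0], a[2]))) for a in self.angles.tolist()}
        return excl

    def nonbonded_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_atoms
        pi, pj = np.triu_indices(n, k=1)
        excl = self.exclusions()
        keep = np.array([(int(a), int(b)) not in excl for a, b in zip(pi, pj)])
        return pi[keep], pj[keep]


@dataclass(frozen=True)
class OracleParams:
    """Parameters of the analytic reference oracle.

    ``kappa`` scales the polarization term; ``r_pol`` is its decay length and
    must stay below the descriptor cutoff so the learnable residual is
    strictly short-ranged. ``bond_perturb``/``angle_perturb`` are the
    fractional offsets of the intra-ligand force constants relative to MM.
    """

    kappa: float = 0.2
    r_pol: float = 2.0
    bond_perturb: float = 0.15
    angle_perturb: float = 0.15

    def validate(self, r_cut: float = 5.0):
        if self.r_pol >= r_cut:
            raise ValueError("r_pol must be smaller than the descriptor cutoff")


@dataclass
class ReferenceRecord:
    """One labelled conformation: oracle outputs and the learning target."""

    frame: AtomicSystem
    e_oracle: float
    f_oracle: np.ndarray        # (n_atoms, 3)
    e_ml_target: float
    f_target: np.ndarray        # (n_atoms, 3), zero outside Q u E'
    force_mask: np.ndarray      # (n_atoms,) bool, Q u E'
    f_target_dprime: np.ndarray  # target forces on the E'' shell (held out)
    dprime_mask: np.ndarray


# ---------------------------------------------------------------------------
# energy terms
# ---------------------------------------------------------------------------

def _bond_energy_forces(pos, bonds, k, r0, forces):
    if bonds.size == 0:
        return 0.0
    d = pos[bonds[:, 1]] - pos[bonds[:, 0]]
    r = np.linalg.norm(d, axis=1)
    dr = r - r0
    e = 0.5 * np.sum(k * dr ** 2)
    fpair = (k * dr / r)[:, None] * d  # force on atom j is -fpair
    np.add.at(forces, bonds[:, 0], fpair)
    np.add.at(forces, bonds[:, 1], -fpair)
    return float(e)


def _angle_energy_forces(pos, angles, k, th0, forces):
    if angles.size == 0:
        return 0.0
    i, j, l = angles[:, 0], angles[:, 1], angles[:, 2]
    u = pos[i] - pos[j]
    v = pos[l] - pos[j]
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ax,ax->a", u, v) / (ru * rv)
    cos = np.clip(cos, -1.0 + 1e-12, 1.0 - 1e-12)
    th = np.arccos(cos)
    dth = th - th0
    e = 0.5 * np.sum(k * dth ** 2)
    sin = np.sqrt(1.0 - cos ** 2)
    # dE/dcos = -k dth / sin;  grad cos as in the angular descriptors
    decos = -k * dth / sin
    gi = v / (ru * rv)[:, None] - (cos / ru ** 2)[:, None] * u
    gl = u / (ru * rv)[:, None] - (cos / rv ** 2)[:, None] * v
    fi = -decos[:, None] * gi
    fl = -decos[:, None] * gl
    np.add.at(forces, i, fi)
    np.add.at(forces, l, fl)
    np.add.at(forces, j, -(fi + fl))
    return float(e)


def _pair_energy_forces(pos, pi, pj, eps, sig, qq, forces,
                        lj: bool = True, coul: bool = True,
                        lj_lambda: float = 1.0, softcore_alpha: float = 0.0):
    """LJ + Coulomb over an explicit pair list; optional soft-core LJ.

    Soft-core form: r^6 in the LJ expression is shifted by
    ``alpha * (1 - lambda) * sigma^6`` and the whole term scaled by lambda,
    removing the singularity as the interaction is decoupled.
    """
    if pi.size == 0:
        return 0.0, 0.0
    d = pos[pi] - pos[pj]
    r2 = np.einsum("px,px->p", d, d)
    r = np.sqrt(r2)
    e_lj = e_c = 0.0
    if lj and eps is not None:
        s6 = sig ** 6
        r6 = r2 ** 3
        denom = r6 + softcore_alpha * (1.0 - lj_lambda) * s6
        x = s6 / denom
        e_pair = lj_lambda * 4.0 * eps * (x ** 2 - x)
        e_lj = float(e_pair.sum())
        # dE/d(r^2): dE/ddenom * 3 r^4
        dEdx = lj_lambda * 4.0 * eps * (2.0 * x - 1.0)
        dxddenom = -s6 / denom ** 2
        dEdr2 = dEdx * dxddenom * 3.0 * r2 ** 2
        fpair = (-2.0 * dEdr2)[:, None] * d  # force on atom pi
        np.add.at(forces, pi, fpair)
        np.add.at(forces, pj, -fpair)
    if coul and qq is not None:
        e_pair = COULOMB_CONSTANT * qq / r
        e_c = float(e_pair.sum())
        fpair = (e_pair / r2)[:, None] * d
        np.add.at(forces, pi, fpair)
        np.add.at(forces, pj, -fpair)
    return e_lj, e_c


def _polarization_energy_forces(pos, qi_idx, qa_idx, charges, kappa, r_pol,
                                forces):
    if qi_idx.size == 0 or qa_idx.size == 0:
        return 0.0
    d = pos[qi_idx][:, None, :] - pos[qa_idx][None, :, :]
    r = np.linalg.norm(d, axis=2)
    qq = kappa * COULOMB_CONSTANT * np.outer(charges[qi_idx], charges[qa_idx])
    e_pair = qq * np.exp(-r / r_pol)
    e = float(e_pair.sum())
    fpair = (e_pair / (r_pol * r))[:, :, None] * d
    np.add.at(forces, qi_idx, fpair.sum(axis=1))
    np.add.at(forces, qa_idx, -fpair.sum(axis=0))
    return e


# ---------------------------------------------------------------------------
# force-field object
# ---------------------------------------------------------------------------

class ToyForceField:
    """MM energies/forces and their QM/MM component decomposition."""

    def __init__(self, topology: ToyTopology):
        self.top = topology
        self._pi, self._pj = topology.nonbonded_pairs()
        eps = topology.lj_eps
        sig = topology.lj_sigma
        self._eps = np.sqrt(eps[self._pi] * eps[self._pj])
        self._sig = 0.5 * (sig[self._pi] + sig[self._pj])
        self._qq = topology.charges[self._pi] * topology.charges[self._pj]

    def _pair_class(self, system: AtomicSystem):
        is_qm = system.regions == "QM"
        qi, qj = is_qm[self._pi], is_qm[self._pj]
        return qi & qj, qi ^ qj, ~qi & ~qj  # QQ, QE, EE pair masks

    def _bonded_class(self, system):
        is_qm = system.regions == "QM"
        b_q = np.all(is_qm[self.top.bonds], axis=1) if self.top.bonds.size \
            else np.zeros(0, bool)
        a_q = np.all(is_qm[self.top.angles], axis=1) if self.top.angles.size \
            else np.zeros(0, bool)
        if self.top.bonds.size and np.any(np.any(is_qm[self.top.bonds], axis=1) & ~b_q):
            raise ValueError("bonded term crossing the QM/MM boundary")
        if self.top.angles.size and np.any(np.any(is_qm[self.top.angles], axis=1) & ~a_q):
            raise ValueError("angle term crossing the QM/MM boundary")
        return b_q, a_q

    def energy_forces(self, system: AtomicSystem):
        """Total MM energy (kJ/mol) and forces (kJ/mol/Å)."""
        pos = system.positions
        forces = np.zeros_like(pos)
        e = _bond_energy_forces(pos, self.top.bonds, self.top.bond_k,
                                self.top.bond_r0, forces)
        e += _angle_energy_forces(pos, self.top.angles, self.top.angle_k,
                                  self.top.angle_theta0, forces)
        e_lj, e_c = _pair_energy_forces(pos, self._pi, self._pj, self._eps,
                                        self._sig, self._qq, forces)
        return e + e_lj + e_c, forces

    def components(self, system: AtomicSystem):
        """Decomposition into intra-Q, Q<->E LJ, Q<->E Coulomb, and environment.

        Returns a dict of (energy, forces) pairs with keys
        ``intra_q``, ``qe_lj``, ``qe_coulomb``, ``env``.
        """
        pos = system.positions
        qq_m, qe_m, ee_m = self._pair_class(system)
        b_q, a_q = self._bonded_class(system)
        out = {}
        # intra-Q: bonded within Q plus nonbonded QQ pairs
        f = np.zeros_like(pos)
        e = _bond_energy_forces(pos, self.top.bonds[b_q], self.top.bond_k[b_q],
                                self.top.bond_r0[b_q], f)
        e += _angle_energy_forces(pos, self.top.angles[a_q],
                                  self.top.angle_k[a_q],
                                  self.top.angle_theta0[a_q], f)
        el, ec = _pair_energy_forces(pos, self._pi[qq_m], self._pj[qq_m],
                                     self._eps[qq_m], self._sig[qq_m],
                                     self._qq[qq_m], f)
        out["intra_q"] = (e + el + ec, f)
        f = np.zeros_like(pos)
        el, _ = _pair_energy_forces(pos, self._pi[qe_m], self._pj[qe_m],
                                    self._eps[qe_m], self._sig[qe_m],
                                    None, f, coul=False)
        out["qe_lj"] = (el, f)
        f = np.zeros_like(pos)
        _, ec = _pair_energy_forces(pos, self._pi[qe_m], self._pj[qe_m],
                                    None, None, self._qq[qe_m], f, lj=False)
        out["qe_coulomb"] = (ec, f)
        f = np.zeros_like(pos)
        e = _bond_energy_forces(pos, self.top.bonds[~b_q], self.top.bond_k[~b_q],
                                self.top.bond_r0[~b_q], f)
        e += _angle_energy_forces(pos, self.top.angles[~a_q],
                                  self.top.angle_k[~a_q],
                                  self.top.angle_theta0[~a_q], f)
        el, ec = _pair_energy_forces(pos, self._pi[ee_m], self._pj[ee_m],
                                     self._eps[ee_m], self._sig[ee_m],
                                     self._qq[ee_m], f)
        out["env"] = (e + el + ec, f)
        return out

    def pair_arrays(self):
        """Nonbonded pair list with combined LJ/charge parameters."""
        return self._pi, self._pj, self._eps, self._sig, self._qq

    def masses(self, system: AtomicSystem) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in system.elements])


def toy_mm_energy_forces(system: AtomicSystem, topology: ToyTopology):
    return ToyForceField(topology).energy_forces(system)


def toy_qm_oracle(system: AtomicSystem, topology: ToyTopology,
                  params: OracleParams = OracleParams()):
    """Analytic stand-in for the QM + electrostatic-embedding energy.

    Perturbed intra-ligand terms + exact Q<->E point-charge Coulomb + the
    short-ranged polarization term. Forces on all atoms.
    """
    q_idx = system.qm_indices
    if q_idx.size == 0:
        raise ValueError("oracle requires a non-empty QM region")
    ff = ToyForceField(topology)
    pos = system.positions
    b_q, a_q = ff._bonded_class(system)
    qq_m, qe_m, _ = ff._pair_class(system)
    forces = np.zeros_like(pos)
    e = _bond_energy_forces(pos, topology.bonds[b_q],
                            topology.bond_k[b_q] * (1.0 + params.bond_perturb),
                            topology.bond_r0[b_q], forces)
    e += _angle_energy_forces(pos, topology.angles[a_q],
                              topology.angle_k[a_q] * (1.0 + params.angle_perturb),
                              topology.angle_theta0[a_q], forces)
    el, ec = _pair_energy_forces(pos, ff._pi[qq_m], ff._pj[qq_m],
                                 ff._eps[qq_m], ff._sig[qq_m], ff._qq[qq_m],
                                 forces)
    e += el + ec
    e_coul, f_coul = coulomb_qm_mm(system)
    e += e_coul
    forces += f_coul
    e += _polarization_energy_forces(pos, q_idx, system.mm_indices,
                                     system.charges, params.kappa,
                                     params.r_pol, forces)
    return e, forces


def build_ml_target(frame: AtomicSystem, topology: ToyTopology,
                    params: OracleParams,
                    partition: RegionPartition | None = None) -> ReferenceRecord:
    """Reference record with the Coulomb-subtracted learning target."""
    if partition is None:
        partition = partition_regions(frame)
    if not np.array_equal(np.sort(partition.Q), frame.qm_indices):
        raise ValueError("partition inconsistent with frame")
    e_oracle, f_oracle = toy_qm_oracle(frame, topology, params)
    e_coul, f_coul = coulomb_qm_mm(frame)
    resid_f = f_oracle - f_coul
    mask = np.zeros(frame.n_atoms, dtype=bool)
    mask[partition.Q] = True
    mask[partition.E_prime] = True
    dmask = np.zeros(frame.n_atoms, dtype=bool)
    dmask[partition.E_dprime] = True
    return ReferenceRecord(
        frame=frame,
        e_oracle=e_oracle,
        f_oracle=f_oracle,
        e_ml_target=e_oracle - e_coul,
        f_target=resid_f * mask[:, None],
        force_mask=mask,
        f_target_dprime=resid_f * dmask[:, None],
        dprime_mask=dmask,
    )


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

_LIG_ELEMENTS = ["C", "O", "C", "H", "S", "Cl"]          # five element types
_LIG_ELEMENTS_RU = ["Ru", "O", "C", "H", "S", "Cl"]      # d-block variant
_LIG_CHARGES = np.array([0.15, -0.35, 0.20, 0.05, -0.10, 0.05])
_LIG_BONDS = np.array([[0, 1], [1, 2], [2, 3], [2, 4], [4, 5]])
_LIG_BOND_R0 = np.array([1.43, 1.43, 1.09, 1.81, 2.05])
_LIG_BOND_K = np.array([2200.0, 2200.0, 2900.0, 1800.0, 1500.0])
_LIG_ANGLES = np.array([[0, 1, 2], [1, 2, 3], [1, 2, 4], [3, 2, 4], [2, 4, 5]])
_LIG_ANGLE_K = np.full(5, 320.0)
_LIG_ANGLE_T0 = np.full(5, np.deg2rad(109.5))

_LJ_BY_ELEMENT = {
    "H": (0.20, 2.40), "C": (0.45, 3.40), "O": (0.70, 3.00),
    "S": (1.05, 3.55), "Cl": (1.10, 3.45), "Ru": (1.50, 2.95),
    "Na": (0.40, 2.60), "F": (0.65, 3.10),
}


def _ligand_geometry(rng: np.random.Generator) -> np.ndarray:
    """Near-equilibrium chain geometry with a small random distortion."""
    pos = np.zeros((6, 3))
    pos[1] = pos[0] + [1.43, 0.0, 0.0]
    pos[2] = pos[1] + [0.48, 1.35, 0.0]
    pos[3] = pos[2] + [-0.36, 0.60, 0.85]
    pos[4] = pos[2] + [1.70, 0.25, -0.55]
    pos[5] = pos[4] + [0.55, 1.60, 1.15]
    return pos + rng.normal(scale=0.03, size=pos.shape)


def _place_particles(rng, n, existing, radius, min_dist=2.2, max_tries=20000):
    placed = []
    pts = list(existing)
    for _ in range(max_tries):
        if len(placed) == n:
            break
        x = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(x) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.asarray(pts) - x, axis=1)) < min_dist:
            continue
        placed.append(x)
        pts.append(x)
    if len(placed) < n:
        raise RuntimeError("could not place solvent particles")
    return np.asarray(placed)


def generate_fixtures(kind: str = "solvated_ligand", n_solvent: int = 30,
                      seed: int = 0, ru_ligand: bool = False):
    """Deterministic toy systems: a solvated ligand or a host-ligand complex.

    The six-atom flexible ligand is the QM region; everything else is MM.
    ``complex`` embeds the ligand in a rigid 12-particle charged LJ pocket.
    """
    if n_solvent < 0:
        raise ValueError("n_solvent must be >= 0")
    rng = np.random.default_rng(seed)
    elements = list(_LIG_ELEMENTS_RU if ru_ligand else _LIG_ELEMENTS)
    pos = _ligand_geometry(rng)
    charges = _LIG_CHARGES.copy()
    groups = ["ligand"] * 6
    if kind == "complex":
        # 12 pocket particles on an icosahedron around the ligand centroid
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([[0, 1, phi], [0, 1, -phi], [0, -1, phi], [0, -1, -phi],
                          [1, phi, 0], [1, -phi, 0], [-1, phi, 0], [-1, -phi, 0],
                          [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]],
                         dtype=float)
        verts /= np.linalg.norm(verts[0])
        host_pos = pos.mean(axis=0) + 5.0 * verts
        host_elem = ["Na", "F"] * 6
        host_q = np.tile([0.30, -0.30], 6)
        elements += host_elem
        pos = np.vstack([pos, host_pos])
        charges = np.concatenate([charges, host_q])
        groups += ["host"] * 12
    elif kind != "solvated_ligand":
        raise ValueError(f"unknown fixture kind {kind!r}")
    if n_solvent:
        radius = max(8.0, (n_solvent / 0.008 * 3.0 / (4.0 * np.pi)) ** (1 / 3))
        sol_pos = _place_particles(rng, n_solvent, list(pos), radius)
        # +-0.15 e keeps a contact ion pair at ~4 kT (300 K): polar-liquid-like
        # structure without glassy, effectively irreversible pairing
        sol_elem = ["Na" if i % 2 == 0 else "F" for i in range(n_solvent)]
        sol_q = np.array([0.15 if i % 2 == 0 else -0.15
                          for i in range(n_solvent)])
        if n_solvent % 2:  # keep the box neutral
            sol_q[-1] = -sol_q[:-1].sum()
        elements += sol_elem
        pos = np.vstack([pos, sol_pos])
        charges = np.concatenate([charges, sol_q])
        groups += ["solvent"] * n_solvent
    n = len(elements)
    regions = ["QM"] * 6 + ["MM"] * (n - 6)
    system = AtomicSystem(elements, pos, regions, charges)
    lj = np.array([_LJ_BY_ELEMENT[e] for e in elements])
    topology = ToyTopology(
        bonds=_LIG_BONDS, bond_k=_LIG_BOND_K, bond_r0=_LIG_BOND_R0,
        angles=_LIG_ANGLES, angle_k=_LIG_ANGLE_K, angle_theta0=_LIG_ANGLE_T0,
        lj_eps=lj[:, 0], lj_sigma=lj[:, 1], charges=charges.copy(),
        groups=np.array(groups, dtype=object),
    )
    return system, topology
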