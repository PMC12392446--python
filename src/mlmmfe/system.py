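"""QM/MM-partitioned atomistic systems and the point-charge Coulomb term.

An :class:`AtomicSystem` holds atoms with element, Cartesian position (Å),
region tag (QM or MM) and a fixed point charge (e) — the MM force-field
charge, carried by QM atoms as well, since it defines the electrostatic
subtraction that makes the learning target short-ranged.

Open (non-periodic) boundaries only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_CONSTANT
from .elements import is_supported

__all__ = [
    "Atom",
    "AtomicSystem",
    "RegionPartition",
    "partition_regions",
    "coulomb_qm_mm",
]

QM = "QM"
MM = "MM"


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    position: np.ndarray  # (3,), Å
    region: str           # "QM" or "MM"
    charge: float         # e

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.region not in (QM, MM):
            raise ValueError(f"atom {self.index}: region must be 'QM' or 'MM'")
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.index}: charge must be finite")
        if not is_supported(self.element):
            raise ValueError(f"atom {self.index}: unsupported element {self.element!r}")


class AtomicSystem:
    """An ordered collection of atoms with vectorized field access.

    Parameters
    ----------
    elements : sequence of str
        Chemical symbols.
    positions : (N, 3) array
        Cartesian coordinates in Å.
    regions : sequence of str
        Per-atom region tag, ``"QM"`` or ``"MM"``.
    charges : (N,) array
        Fixed point charges in e.
    """

    def __init__(self, elements, positions, regions, charges):
        self.elements = list(elements)
        self.positions = np.array(positions, dtype=float)
        self.regions = np.asarray(regions, dtype=object)
        self.charges = np.array(charges, dtype=float)
        n = len(self.elements)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.regions.shape != (n,) or self.charges.shape != (n,):
            raise ValueError("regions/charges length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite position")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("non-finite charge")
        for e in self.elements:
            if not is_supported(e):
                raise ValueError(f"unsupported element {e!r}")
        bad = [r for r in self.regions if r not in (QM, MM)]
        if bad:
            raise ValueError(f"invalid region tags: {set(bad)}")

    # -- convenience ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def qm_indices(self) -> np.ndarray:
        return np.flatnonzero(self.regions == QM)

    @property
    def mm_indices(self) -> np.ndarray:
        return np.flatnonzero(self.regions == MM)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(i, self.elements[i], self.positions[i], self.regions[i],
                 self.charges[i])
            for i in range(len(self))
        ]

    def with_positions(self, positions: np.ndarray) -> "AtomicSystem":
        """A copy of this system at new coordinates (same elements/regions/charges)."""
        return AtomicSystem(self.elements, positions, self.regions, self.charges)

    def copy(self) -> "AtomicSystem":
        return self.with_positions(self.positions.copy())


@dataclass(frozen=True)
class RegionPartition:
    """Index sets of the QM/MM partition.

    ``E_prime`` are MM atoms closer than ``r_cut`` to any QM atom: they enter
    the descriptors and carry ML forces. ``E_dprime`` is the validation shell
    just outside the cutoff (``r_cut <= d <= r_cut + shell``), used to verify
    that the cutoff suffices; it never enters training.
    """

    Q: np.ndarray
    E: np.ndarray
    E_prime: np.ndarray
    E_dprime: np.ndarray
    r_cut: float = 5.0
    shell: float = 1.0

    def __post_init__(self):
        q, e = set(self.Q.tolist()), set(self.E.tolist())
        if q & e:
            raise ValueError("Q and E overlap")
        if not set(self.E_prime.tolist()) <= e or not set(self.E_dprime.tolist()) <= e:
            raise ValueError("E' and E'' must be subsets of E")
        if set(self.E_prime.tolist()) & set(self.E_dprime.tolist()):
            raise ValueError("E' and E'' overlap")


def partition_regions(system: AtomicSystem, r_cut: float = 5.0,
                      shell: float = 1.0) -> RegionPartition:
    """Partition MM atoms into the in-cutoff region E' and the validation shell E''.

    Boundary convention: E' is strictly inside the cutoff (d < r_cut); an MM
    atom exactly at the cutoff belongs to the shell E''.
    """
    if r_cut <= 0 or shell <= 0:
        raise ValueError("r_cut and shell must be positive")
    q_idx = system.qm_indices
    e_idx = system.mm_indices
    if q_idx.size == 0:
        raise ValueError("system has no QM atoms")
    if e_idx.size == 0:
        dmin = np.empty((0,))
    else:
        dmin = cdist(system.positions[e_idx], system.positions[q_idx]).min(axis=1)
    e_prime = e_idx[dmin < r_cut]
    e_dprime = e_idx[(dmin >= r_cut) & (dmin <= r_cut + shell)]
    return RegionPartition(q_idx, e_idx, e_prime, e_dprime, r_cut, shell)


def coulomb_qm_mm(system: AtomicSystem):
    """Point-charge Coulomb energy and forces between the QM and MM regions.

    The full (uncut) sum ``k_e * sum_{I in Q} sum_{A in E} q_I q_A / r_IA``.
    This is the term subtracted from the reference energy so that the learning
    target is short-ranged.

    Returns
    -------
    energy : float, kJ/mol
    forces : (n_atoms, 3) array, kJ/mol/Å — exact negative gradient.
    """
    q_idx = system.qm_indices
    e_idx = system.mm_indices
    forces = np.zeros((system.n_atoms, 3))
    if q_idx.size == 0 or e_idx.size == 0:
        return 0.0, forces
    rq = system.positions[q_idx]          # (nq, 3)
    re = system.positions[e_idx]          # (ne, 3)
    diff = rq[:, None, :] - re[None, :, :]  # (nq, ne, 3), R_I - R_A
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < 1e-10):
        raise ValueError("coincident QM-MM atom pair: Coulomb singularity")
    qq = COULOMB_CONSTANT * np.outer(system.charges[q_idx], system.charges[e_idx])
    energy = float(np.sum(qq / r))
    # F_I = k q_I q_A (R_I - R_A) / r^3 ; Newton's third law for F_A
    pair_f = (qq / r**3)[:, :, None] * diff
    forces[q_idx] += pair_f.sum(axis=1)
    forces[e_idx] -= pair_f.sum(axis=0)
    return energy, forces
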