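"""File formats: extended-XYZ dialect, topology text, HDF5 containers.

The extended-XYZ dialect carries per-atom columns
``species:S:1:pos:R:3:region:S:1:charge:R:1`` and optionally ``forces:R:3``;
the comment line holds ``key=value`` metadata (energy, frame id, lambda,
...). Positions round-trip losslessly to >= 12 significant digits.

Topologies are stored as a sectioned plain-text format with ``[bonds]``,
``[angles]``, ``[lj]``, ``[charges]`` and ``[groups]`` blocks.

Trained committees and featurized datasets go into single-file HDF5
containers with an embedded schema version and the producing configuration.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .descriptors import DescriptorConfig, DescriptorJacobian
from .nnp import EnsembleModel, Frame, HDNNPModel, TrainingDataset
from .system import AtomicSystem
from .toy import ToyTopology

__all__ = [
    "read_extxyz",
    "write_extxyz",
    "read_topology",
    "write_topology",
    "save_ensemble",
    "load_ensemble",
    "save_dataset",
    "load_dataset",
]

_PROPS_PLAIN = "species:S:1:pos:R:3:region:S:1:charge:R:1"
_PROPS_FORCES = _PROPS_PLAIN + ":forces:R:3"


def _fmt(x: float) -> str:
    return format(float(x), ".15g")


def _fmt_meta(v) -> str:
    if isinstance(v, str):
        return f'"{v}"' if " " in v else v
    if isinstance(v, (float, np.floating)):
        return _fmt(v)
    return str(v)


def _parse_meta(comment: str) -> dict:
    meta = {}
    # tokenizer honoring double quotes
    tokens, cur, quoted = [], "", False
    for ch in comment.strip():
        if ch == '"':
            quoted = not quoted
        elif ch == " " and not quoted:
            if cur:
                tokens.append(cur)
            cur = ""
        else:
            cur += ch
    if cur:
        tokens.append(cur)
    for tok in tokens:
        if "=" not in tok:
            continue
        k, v = tok.split("=", 1)
        try:
            meta[k] = int(v)
        except ValueError:
            try:
                meta[k] = float(v)
            except ValueError:
                meta[k] = v
    return meta


def write_extxyz(path, frames, metadata=None, forces=None, mode="w"):
    """Write one or more systems; ``frames`` is an AtomicSystem or a list.

    ``metadata``/``forces`` are per-frame lists (or single values) matching
    ``frames``.
    """
    if isinstance(frames, AtomicSystem):
        frames = [frames]
        metadata = [metadata] if metadata is not None else None
        forces = [forces] if forces is not None else None
    with open(path, mode) as fh:
        for i, system in enumerate(frames):
            meta = dict(metadata[i]) if metadata and metadata[i] else {}
            frc = forces[i] if forces is not None else None
            props = _PROPS_FORCES if frc is not None else _PROPS_PLAIN
            meta_str = " ".join(f"{k}={_fmt_meta(v)}" for k, v in meta.items())
            fh.write(f"{system.n_atoms}\n")
            fh.write(f"Properties={props}" + (f" {meta_str}" if meta_str else "")
                     + "\n")
            for a in range(system.n_atoms):
                cols = [system.elements[a],
                        *(_fmt(x) for x in system.positions[a]),
                        system.regions[a], _fmt(system.charges[a])]
                if frc is not None:
                    cols += [_fmt(x) for x in frc[a]]
                fh.write(" ".join(cols) + "\n")


def read_extxyz(path):
    """Read all frames; returns a list of (AtomicSystem, metadata) pairs.

    Forces, when present, are returned under ``metadata["forces"]``.
    """
    out = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        comment = lines[pos + 1]
        if "Properties=" not in comment:
            raise ValueError("missing Properties declaration")
        props = comment.split("Properties=", 1)[1].split()[0]
        if not props.startswith(_PROPS_PLAIN):
            raise ValueError(
                f"unsupported column layout {props!r}; expected "
                f"{_PROPS_PLAIN!r} (region and charge columns are required)")
        has_forces = props == _PROPS_FORCES
        meta = _parse_meta(comment.replace(f"Properties={props}", ""))
        elements, coords, regions, charges, forces = [], [], [], [], []
        for a in range(n):
            cols = lines[pos + 2 + a].split()
            elements.append(cols[0])
            coords.append([float(c) for c in cols[1:4]])
            regions.append(cols[4])
            charges.append(float(cols[5]))
            if has_forces:
                forces.append([float(c) for c in cols[6:9]])
        system = AtomicSystem(elements, np.array(coords), regions,
                              np.array(charges))
        if has_forces:
            meta["forces"] = np.array(forces)
        out.append((system, meta))
        pos += 2 + n
    return out


# ---------------------------------------------------------------------------
# topology text format
# ---------------------------------------------------------------------------

def write_topology(path, top: ToyTopology):
    with open(path, "w") as fh:
        fh.write("[bonds]\n")
        for (i, j), k, r0 in zip(top.bonds, top.bond_k, top.bond_r0):
            fh.write(f"{i} {j} {_fmt(k)} {_fmt(r0)}\n")
        fh.write("[angles]\n")
        for (i, j, l), k, t0 in zip(top.angles, top.angle_k, top.angle_theta0):
            fh.write(f"{i} {j} {l} {_fmt(k)} {_fmt(t0)}\n")
        fh.write("[lj]\n")
        for e, s in zip(top.lj_eps, top.lj_sigma):
            fh.write(f"{_fmt(e)} {_fmt(s)}\n")
        fh.write("[charges]\n")
        for q in top.charges:
            fh.write(f"{_fmt(q)}\n")
        fh.write("[groups]\n")
        for g in top.groups:
            fh.write(f"{g}\n")


def read_topology(path) -> ToyTopology:
    sections: dict[str, list[list[str]]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                sections[current] = []
            elif current is not None:
                sections[current].append(line.split())
    for name in ("bonds", "angles", "lj", "charges", "groups"):
        if name not in sections:
            raise ValueError(f"topology file missing [{name}] section")
    bonds = np.array([[int(r[0]), int(r[1])] for r in sections["bonds"]],
                     dtype=int).reshape(-1, 2)
    lj = np.array([[float(r[0]), float(r[1])] for r in sections["lj"]])
    angles = np.array([[int(r[0]), int(r[1]), int(r[2])]
                       for r in sections["angles"]], dtype=int).reshape(-1, 3)
    return ToyTopology(
        bonds=bonds,
        bond_k=np.array([float(r[2]) for r in sections["bonds"]]),
        bond_r0=np.array([float(r[3]) for r in sections["bonds"]]),
        angles=angles,
        angle_k=np.array([float(r[3]) for r in sections["angles"]]),
        angle_theta0=np.array([float(r[4]) for r in sections["angles"]]),
        lj_eps=lj[:, 0], lj_sigma=lj[:, 1],
        charges=np.array([float(r[0]) for r in sections["charges"]]),
        groups=np.array([r[0] for r in sections["groups"]], dtype=object),
    )


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _config_to_json(config: DescriptorConfig) -> str:
    return json.dumps({
        "eta_rad": list(config.eta_rad), "eta_ang": list(config.eta_ang),
        "lambda_vals": list(config.lambda_vals),
        "zeta_vals": list(config.zeta_vals), "r_cut": config.r_cut,
        "q_max": config.q_max, "qmmm_mode": config.qmmm_mode,
    })


def _config_from_json(s: str) -> DescriptorConfig:
    d = json.loads(s)
    return DescriptorConfig(
        eta_rad=tuple(d["eta_rad"]), eta_ang=tuple(d["eta_ang"]),
        lambda_vals=tuple(d["lambda_vals"]), zeta_vals=tuple(d["zeta_vals"]),
        r_cut=d["r_cut"], q_max=d["q_max"], qmmm_mode=d["qmmm_mode"])


def save_ensemble(path, ensemble: EnsembleModel, config_hash: str = ""):
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = _SCHEMA_VERSION
        fh.attrs["descriptor_config"] = _config_to_json(ensemble.config)
        fh.attrs["rmse_floor_energy"] = ensemble.rmse_floor_energy
        fh.attrs["rmse_floor_force"] = ensemble.rmse_floor_force
        fh.attrs["c"] = ensemble.c
        fh.attrs["config_hash"] = config_hash
        for p, m in enumerate(ensemble.members):
            g = fh.create_group(f"member_{p}")
            g.attrs["elements"] = json.dumps(m.elements)
            g.attrs["hidden"] = list(m.hidden)
            g.attrs["init_seed"] = m.init_seed
            g.create_dataset("x_mean", data=m.x_mean)
            g.create_dataset("x_std", data=m.x_std)
            g.attrs["y_mean"] = m.y_mean
            g.attrs["y_std"] = m.y_std
            for e, params in m.nets.items():
                ge = g.create_group(f"net_{e}")
                for k, v in params.items():
                    ge.create_dataset(k, data=v)


def load_ensemble(path) -> EnsembleModel:
    with h5py.File(path, "r") as fh:
        config = _config_from_json(fh.attrs["descriptor_config"])
        members = []
        p = 0
        while f"member_{p}" in fh:
            g = fh[f"member_{p}"]
            elements = json.loads(g.attrs["elements"])
            m = HDNNPModel(elements, tuple(int(h) for h in g.attrs["hidden"]),
                           config, init_seed=int(g.attrs["init_seed"]))
            m.x_mean = g["x_mean"][...]
            m.x_std = g["x_std"][...]
            m.y_mean = float(g.attrs["y_mean"])
            m.y_std = float(g.attrs["y_std"])
            for e in elements:
                ge = g[f"net_{e}"]
                m.nets[e] = {k: ge[k][...] for k in
                             ("W1", "b1", "W2", "b2", "w3", "b3")}
            members.append(m)
            p += 1
        return EnsembleModel(members,
                             float(fh.attrs["rmse_floor_energy"]),
                             float(fh.attrs["rmse_floor_force"]),
                             float(fh.attrs["c"]))


def save_dataset(path, dataset: TrainingDataset, config_hash: str = ""):
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = _SCHEMA_VERSION
        fh.attrs["descriptor_config"] = _config_to_json(dataset.config)
        fh.attrs["config_hash"] = config_hash
        fh.create_dataset("train_idx", data=dataset.train_idx)
        fh.create_dataset("test_idx", data=dataset.test_idx)
        for i, f in enumerate(dataset.frames):
            g = fh.create_group(f"frame_{i:06d}")
            g.attrs["frame_id"] = f.frame_id
            g.attrs["e_target"] = f.e_target
            g.attrs["n_atoms"] = f.n_atoms
            g.attrs["qm_elements"] = json.dumps(f.qm_elements)
            g.create_dataset("features", data=f.features)
            g.create_dataset("f_target", data=f.f_target)
            g.create_dataset("force_mask", data=f.force_mask)
            for c, jac in enumerate(f.jacobians):
                gj = g.create_group(f"jac_{c}")
                gj.attrs["center"] = jac.center
                gj.create_dataset("atom_indices", data=jac.atom_indices)
                gj.create_dataset("values", data=jac.values)


def load_dataset(path) -> TrainingDataset:
    with h5py.File(path, "r") as fh:
        config = _config_from_json(fh.attrs["descriptor_config"])
        frames = []
        names = sorted(k for k in fh.keys() if k.startswith("frame_"))
        for name in names:
            g = fh[name]
            jacs = []
            c = 0
            while f"jac_{c}" in g:
                gj = g[f"jac_{c}"]
                jacs.append(DescriptorJacobian(int(gj.attrs["center"]),
                                               gj["atom_indices"][...],
                                               gj["values"][...]))
                c += 1
            frames.append(Frame(
                features=g["features"][...], jacobians=jacs,
                qm_elements=json.loads(g.attrs["qm_elements"]),
                n_atoms=int(g.attrs["n_atoms"]),
                e_target=float(g.attrs["e_target"]),
                f_target=g["f_target"][...],
                force_mask=g["force_mask"][...].astype(bool),
                frame_id=int(g.attrs["frame_id"])))
        ds = TrainingDataset(frames, config)
        ds.train_idx = fh["train_idx"][...]
        ds.test_idx = fh["test_idx"][...]
        return ds
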