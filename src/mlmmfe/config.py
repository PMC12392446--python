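"""Run configuration: schema-validated YAML with a reproducibility hash."""

from __future__ import annotations

import hashlib

import yaml

__all__ = ["RunConfig", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "fixture": {"kind": "solvated_ligand", "n_solvent": 30,
                "ru_ligand": False},
    "descriptor": {"eta_rad": [0.5, 1.0, 2.0, 4.0, 8.0],
                   "eta_ang": [1.0, 4.0], "lambda_vals": [1, -1],
                   "zeta_vals": [1.0, 4.0, 16.0], "r_cut": 5.0,
                   "q_max": 1.0, "qmmm_mode": True},
    "oracle": {"kappa": 0.2, "r_pol": 2.0, "bond_perturb": 0.15,
               "angle_perturb": 0.15},
    "training": {"n_frames": 2000, "stride": 10, "hidden": None,
                 "n_members": 10, "epochs": 1000, "w_e": 1.0, "w_f": 0.1,
                 "lr": 5.0e-3, "test_fraction": 0.1},
    "md": {"dt": 1.0, "friction": 0.02, "temperature": 300.0},
    "protocol": {"t_switch": 1.0, "t_equil": 1.0, "n_switches": 30,
                 "n_segments": 100},
    "afe": {"lambdas": [0.0, 0.25, 0.5, 0.75, 1.0], "n_samples": 200,
            "stride": 10, "n_equil_steps": 200, "softcore_alpha": 0.5},
    "active_learning": {"energy_threshold": 3.0, "force_threshold": 3.0,
                        "min_time_separation": 0.05, "per_iteration_cap": 25,
                        "convergence_new_structures": 10, "base_epochs": 1000,
                        "final_epochs": 5000, "max_iterations": 10,
                        "n_repeats": 6},
}


class RunConfig:
    """Nested configuration; unknown sections or keys are rejected."""

    def __init__(self, data: dict | None = None):
        self.data = _merge_validate(DEFAULT_CONFIG, data or {})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def __getitem__(self, key):
        return self.data[key]

    @property
    def hash(self) -> str:
        canon = yaml.safe_dump(self.data, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _merge_validate(defaults, override, path=""):
    if not isinstance(override, dict):
        raise ValueError(f"section {path or '<root>'} must be a mapping")
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} "
                         f"in section {path or '<root>'}")
    out = {}
    for k, v in defaults.items():
        if k in override and isinstance(v, dict):
            out[k] = _merge_validate(v, override[k], f"{path}{k}.")
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    return out
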