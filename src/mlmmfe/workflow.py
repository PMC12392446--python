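"""Dataset construction: from MD sampling to featurized training frames.

Initial training data come from MM molecular dynamics of the physical end
states; frames are extracted with a time stride (to reduce correlation),
labelled by the reference oracle, Coulomb-subtracted into learning targets,
and featurized into descriptor vectors and Jacobians.
"""

from __future__ import annotations

import numpy as np

from .descriptors import DescriptorConfig, featurize
from .md import LangevinParams, MMPotential, run_md
from .nnp import Frame, TrainingDataset
from .system import AtomicSystem, partition_regions
from .toy import OracleParams, ToyTopology, build_ml_target

__all__ = [
    "frame_from_system",
    "frames_from_positions",
    "initial_dataset",
    "movable_mask",
]


def movable_mask(topology) -> np.ndarray:
    """All atoms move except the rigid host pocket."""
    return np.array([g != "host" for g in topology.groups])


def frame_from_system(system: AtomicSystem, topology: ToyTopology,
                      oracle_params: OracleParams, config: DescriptorConfig,
                      frame_id: int = -1) -> Frame:
    """Label one conformation with the oracle and featurize it."""
    partition = partition_regions(system, config.r_cut)
    rec = build_ml_target(system, topology, oracle_params, partition)
    G, jacs = featurize(system, partition, config, gradients=True)
    return Frame(
        features=G,
        jacobians=jacs,
        qm_elements=[system.elements[i] for i in partition.Q],
        n_atoms=system.n_atoms,
        e_target=rec.e_ml_target,
        f_target=rec.f_target,
        force_mask=rec.force_mask,
        frame_id=frame_id,
    )


def frames_from_positions(template: AtomicSystem, positions_list,
                          topology: ToyTopology, oracle_params: OracleParams,
                          config: DescriptorConfig,
                          first_id: int = 0) -> list[Frame]:
    return [frame_from_system(template.with_positions(p), topology,
                              oracle_params, config, first_id + i)
            for i, p in enumerate(positions_list)]


def initial_dataset(template: AtomicSystem, topology: ToyTopology,
                    oracle_params: OracleParams, config: DescriptorConfig,
                    n_frames: int, params: LangevinParams, stride: int = 10,
                    n_equil_steps: int = 500, test_fraction: float = 0.1,
                    split_seed: int = 0) -> TrainingDataset:
    """Sample end-state MM dynamics and build the base training set.

    Runs ``n_frames * stride`` production steps after equilibration; frames
    are taken every ``stride`` steps so that successive training
    conformations are separated in time.
    """
    oracle_params.validate(config.r_cut)
    pot = MMPotential(template, topology)
    mov = movable_mask(topology)
    eq = run_md(template, pot, params, n_equil_steps,
                stride=n_equil_steps, movable=mov)
    prod_params = LangevinParams(params.dt, params.friction,
                                 params.temperature, params.seed + 1,
                                 params.masses)
    traj = run_md(template.with_positions(eq.final_positions), pot,
                  prod_params, n_frames * stride, stride=stride, movable=mov,
                  velocities=eq.final_velocities)
    frames = frames_from_positions(template, traj.positions, topology,
                                   oracle_params, config)
    return TrainingDataset(frames, config, test_fraction=test_fraction,
                           split_seed=split_seed)
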