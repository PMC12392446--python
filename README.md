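# mlmmfe

Machine-learning-enhanced binding free energies for QM/MM-partitioned
systems: charge-aware element-embracing atomic descriptors, committees of
high-dimensional neural-network potentials (HDNNPs) trained by active
learning, and alchemical free energies with nonequilibrium MM → ML/MM
end-state corrections.

## Who this is for

Computational chemists who want a transparent, desk-scale implementation of
the ML/MM end-state-correction workflow: every stage — descriptor
construction, potential training, uncertainty-driven data collection,
λ-state sampling, nonequilibrium switching, and free-energy estimation —
is a plain Python object that can be inspected, tested, and rerun from a
seed. The package ships its own toy host–ligand–solvent systems with an
analytic reference oracle, so the full pipeline runs in minutes with no
external quantum-chemistry or MD engine.

## The model

A hybrid QM/MM system is split into a quantum region Q (the ligand) and an
MM environment E. The ML potential learns the QM energy plus its
electrostatic embedding, with the point-charge Coulomb sum subtracted so
that the target is short-ranged:

    E_ML = E_QM + E_elec^int − k_e Σ_{I∈Q} Σ_{A∈E} q_I q_A / r_IA

Each QM atom's environment is encoded by element-embracing atom-centered
symmetry functions: invariant radial/angular features whose element
dependence enters through seven periodic-table channels (1, n, m, d, n̄, m̄,
d̄) rather than per-element blocks — the vector length does not grow with
the number of chemical elements. QM/MM interaction masks and charge
channels extend the descriptor to the mixed system, with MM neighbors
represented by their point charge alone. A per-element two-hidden-layer
network maps descriptors to atomic energies; a committee of such models
yields the prediction (mean) and its uncertainty (RMSE-floored spread):

    ΔĒ = max{ RMSE_test , [ c²/(N−1) Σ_p (E_p − Ē)² ]^½ }

High-uncertainty structures encountered during ML/MM simulation are
relabelled by the reference method and retrained (query-by-committee
active learning). Binding free energies combine MM alchemical decoupling
(MBAR over λ states) with BAR over nonequilibrium MM → ML/MM switching
work at both end states:

    ΔG_bind^ML/MM = ΔG_complex^MM + ΔG_PL+S^ML/MM − ΔG_solv^MM − ΔG_L+S^ML/MM

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import numpy as np
from mlmmfe import (DescriptorConfig, HDNNPEnsemble, LangevinParams,
                    OracleParams, generate_fixtures, descriptor_size)
from mlmmfe.workflow import initial_dataset

# a 6-atom ligand (QM) in a droplet of 20 charged LJ particles (MM)
system, topology = generate_fixtures("solvated_ligand", n_solvent=20, seed=5)

config = DescriptorConfig(eta_rad=(1.0, 4.0, 16.0, 48.0),
                          eta_ang=(1.0, 8.0),
                          lambda_vals=(1, -1), zeta_vals=(1.0,))
print(descriptor_size(config, mode="eeacsf_qmmm"))
# (32, 76, 108)  -> 32 radial + 76 angular = 108 features per QM atom
# (in plain eeACSF mode the same hyperparameters give 28 + 44 = 72)

dataset = initial_dataset(system, topology, OracleParams(), config,
                          n_frames=500, params=LangevinParams(seed=11),
                          stride=5)
result = HDNNPEnsemble(dataset, hidden=(14, 14), n_members=2).fit(
    epochs=600, seed=0, loss_weights=(1.0, 0.02))
print(result.summary())
```

prints (timings vary):

```
HDNNP ensemble fit
==============================================
members: 2
member    E test RMSE    F test RMSE
     0         0.3602        12.4015
     1         0.3689        11.9510
----------------------------------------------
energy RMSE floor: 2.1873 kJ/mol (total energy)
force RMSE floor:  12.1763 kJ/mol/Å
```

The per-member energy RMSE is per QM atom on held-out conformations
(0.36 kJ/mol per atom here, ≈ 2.2 kJ/mol for the six-atom ligand); the
floors are the minimum uncertainty the committee will ever report —
claiming a prediction tighter than the test error would be fiction. The committee can
then drive ML/MM dynamics, λ sampling and nonequilibrium switching
(`mlmmfe.md`), and the estimators in `mlmmfe.estimators` turn the sampled
reduced energies and work sets into free energies with bootstrap errors.

The same pipeline is scriptable from the shell:

```bash
mlmmfe fixtures  --out system.extxyz --topology-out topology.txt
mlmmfe featurize --frames system.extxyz --topology topology.txt --out data.h5
mlmmfe train     --dataset data.h5 --out model.h5
mlmmfe neq       --topology topology.txt --model model.h5
mlmmfe cycle     --dg-complex-mm -12.0 --dg-solv-mm -5.0
```

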