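import numpy as np
import pytest

from micromet import _kernels as _k
from micromet.cytokine_diffusion import DiffusionParams
from micromet.model_core import LatticeConfig, ModelParameters
from micromet.simulation_engine import SimulationConfig
from micromet.state import SimulationState


@pytest.fixture
def small_lattice():
    return LatticeConfig(side_lengths=(5, 5, 5), voxel_edge_um=10.0, dt_min=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def state_factory():
    """Build a small SimulationState with given parameter overrides."""

    def make(side=5, seed=0, **param_overrides):
        lattice = LatticeConfig(side_lengths=(side, side, side))
        defaults = dict(initial_dcs=0, initial_macrophages=0,
                        initial_cancer_cells=1, abort_threshold=10 ** 6)
        defaults.update(param_overrides)
        params = ModelParameters(**defaults)
        state = SimulationState(lattice, params)
        _k.seed_rng(seed)
        return state

    return make


@pytest.fixture
def growth_only_config():
    """7^3 lattice, single cancer cell, no death/migration/mutation/immune."""
    return SimulationConfig(
        lattice=LatticeConfig(side_lengths=(7, 7, 7)),
        params=ModelParameters(
            initial_cancer_cells=1, initial_dcs=0, initial_macrophages=0,
            p_death=0.0, p_migration_cancer=0.0, p_mutation=0.0,
            t_proliferation=5, abort_threshold=10 ** 6),
        diffusion=DiffusionParams(d_enh=0.0, d_sup=0.0, lambda_decay=0.0),
        duration_steps=16, metastasis_threshold=700)
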