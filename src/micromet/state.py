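"""Structure-of-arrays simulation state and initial-state construction."""

from __future__ import annotations

import numpy as np

from . import _kernels as _k
from .model_core import (
    CANCER, CTL, DC, HELPER, KIND_NAMES, MACROPHAGE, SUPPRESSOR,
    AntigenGenotype, CellRecord, LatticeConfig, ModelParameters,
)


class SimulationState:
    """Mutable state of one simulation replica.

    Agents live in flat arrays of capacity ``n_voxels`` (one cell per voxel
    bounds the population); ``occ`` maps voxels to agent ids (-1 = vacant),
    ``debris`` holds per-voxel antigen bitmasks of uncollected tumor debris
    (debris coexists with cells and does not occupy the lattice).
    """

    def __init__(self, lattice: LatticeConfig, params: ModelParameters):
        self.lattice = lattice
        self.params = params
        cap = lattice.n_voxels
        self.occ = np.full(cap, -1, dtype=np.int64)
        self.debris = np.zeros(cap, dtype=np.int64)
        self.kind = np.zeros(cap, dtype=np.int64)
        self.pos = np.zeros(cap, dtype=np.int64)
        self.geno = np.zeros(cap, dtype=np.int64)
        self.spec = np.full(cap, -1, dtype=np.int64)
        self.age = np.zeros(cap, dtype=np.int64)
        self.immobile = np.zeros(cap, dtype=np.int64)
        self.prolif = np.zeros(cap, dtype=np.int64)
        self.activated = np.zeros(cap, dtype=np.bool_)
        self.alive = np.zeros(cap, dtype=np.bool_)
        self.born = np.full(cap, -1, dtype=np.int64)
        self.free_stack = np.arange(cap - 1, -1, -1, dtype=np.int64)
        self.meta = np.zeros(_k.N_META, dtype=np.int64)
        self.meta[_k.M_FREE_TOP] = cap
        self.enh = np.zeros(cap, dtype=np.float64)
        self.sup = np.zeros(cap, dtype=np.float64)
        self.queues = np.zeros((params.t_delay, _k.N_ANTIGENS), dtype=np.float64)
        self.step = 0
        # scratch buffers for the kernels
        self._tmp = np.zeros(cap, dtype=np.float64)
        self._nbuf = np.zeros(32, dtype=np.int64)
        self._obuf = np.zeros(32, dtype=np.int64)
        self._ids = np.zeros(cap, dtype=np.int64)
        self._emitted = np.zeros(_k.N_ANTIGENS, dtype=np.float64)

    # -- agent management ---------------------------------------------------

    def add_agent(self, kind: int, voxel, genotype_mask: int = 0,
                  specificity: int = -1) -> int:
        """Place one agent; ``voxel`` is a position triple or flat index."""
        v = voxel if np.isscalar(voxel) else self.lattice.flat_index(tuple(voxel))
        if self.occ[v] >= 0:
            raise ValueError(f"voxel {voxel} already occupied")
        i = int(_k._spawn(kind, v, genotype_mask, specificity, self.step,
                          self.occ, self.kind, self.pos, self.geno, self.spec,
                          self.age, self.immobile, self.prolif, self.activated,
                          self.alive, self.born, self.free_stack, self.meta))
        if i < 0:
            raise RuntimeError("lattice full")
        self.born[i] = -1  # pre-existing agents act from the current step
        return i

    def counts(self) -> dict[str, int]:
        c = np.bincount(self.kind[self.alive], minlength=7)
        return {name: int(c[code]) for code, name in KIND_NAMES.items()}

    @property
    def n_agents(self) -> int:
        return int(self.alive.sum())

    def cancer_count(self) -> int:
        return int(np.count_nonzero(self.kind[self.alive] == CANCER))

    def agent_record(self, i: int) -> CellRecord:
        return CellRecord(
            kind=KIND_NAMES[int(self.kind[i])],
            position=self.lattice.unflat(int(self.pos[i])),
            genotype=AntigenGenotype(int(self.geno[i])) if self.kind[i] == CANCER else None,
            specificity=int(self.spec[i]),
            age=int(self.age[i]),
            immobile_until=int(self.immobile[i]),
            activated=bool(self.activated[i]),
            proliferation_timer=int(self.prolif[i]),
        )

    def occupancy_consistent(self) -> bool:
        """Occupancy bijection: occupied voxels == live agents, positions match."""
        occupied = np.flatnonzero(self.occ >= 0)
        ids = self.occ[occupied]
        if len(occupied) != self.n_agents:
            return False
        if not self.alive[ids].all():
            return False
        return bool((self.pos[ids] == occupied).all())

    def seed_kernel_rng(self, seed: int) -> None:
        _k.seed_rng(int(seed) % (2 ** 31 - 1))


def build_initial_state(config, rng: np.random.Generator) -> SimulationState:
    """Initial state: a compact centered cancer colony sharing the baseline
    antigen (index 0), plus uniformly scattered DCs and macrophages.

    ``config`` is a :class:`~micromet.simulation_engine.SimulationConfig`.
    The colony is the first ``initial_cancer_cells`` voxels of a centered
    cube (5x5x5 for the default 125 cells).
    """
    lattice: LatticeConfig = config.lattice
    params: ModelParameters = config.params
    n0 = params.initial_cancer_cells
    n_extra = params.initial_dcs + params.initial_macrophages
    if n0 + n_extra > lattice.n_voxels:
        raise ValueError("initial populations exceed lattice capacity")
    state = SimulationState(lattice, params)

    side = int(np.ceil(round(n0 ** (1.0 / 3.0), 9)))
    nx, ny, nz = lattice.side_lengths
    if side > min(nx, ny, nz):
        raise ValueError("initial cancer colony does not fit in the lattice")
    ox, oy, oz = ((nx - side) // 2, (ny - side) // 2, (nz - side) // 2)
    placed = 0
    for dz in range(side):
        for dy in range(side):
            for dx in range(side):
                if placed >= n0:
                    break
                state.add_agent(CANCER, (ox + dx, oy + dy, oz + dz),
                                genotype_mask=1)
                placed += 1

    free = np.flatnonzero(state.occ < 0)
    if n_extra > len(free):
        raise ValueError("not enough vacant voxels for DCs/macrophages")
    chosen = rng.choice(free, size=n_extra, replace=False)
    for v in chosen[: params.initial_dcs]:
        state.add_agent(DC, int(v))
    for v in chosen[params.initial_dcs:]:
        state.add_agent(MACROPHAGE, int(v))
    return state
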