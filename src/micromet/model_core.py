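"""Lattice geometry, agent records, model configuration and movement primitives.

The tumor microenvironment (TME) is a cubic lattice of voxels, each holding at
most one cell agent.  Cells interact with the voxels at Chebyshev distance 1
(the 3D Moore neighborhood, 26 voxels in the interior).  Boundaries are hard
walls: recruitment explicitly injects immune cells "at the border", which
periodic boundaries would break.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: Number of distinct tumor antigens in the finite-allele mutation model.
N_ANTIGENS = 32

# Agent kind codes shared with the numba kernels.
EMPTY, CANCER, CTL, DC, MACROPHAGE, HELPER, SUPPRESSOR = 0, 1, 2, 3, 4, 5, 6

KIND_NAMES = {
    CANCER: "cancer",
    CTL: "ctl",
    DC: "dc",
    MACROPHAGE: "macrophage",
    HELPER: "helper",
    SUPPRESSOR: "suppressor",
}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and time discretization of the simulated tissue block.

    ``side_lengths`` are voxels per axis (x, y, z); ``voxel_edge_um`` is the
    voxel edge in micrometers; ``dt_min`` the duration of one agent step in
    minutes.  Defaults give the 100x100x100 x 10 um = 1 mm^3 block stepped at
    10 min.
    """

    side_lengths: tuple[int, int, int] = (100, 100, 100)
    voxel_edge_um: float = 10.0
    dt_min: float = 10.0

    def __post_init__(self):
        if len(self.side_lengths) != 3 or any(s < 3 for s in self.side_lengths):
            raise ValueError("side_lengths must be three integers >= 3")
        if self.voxel_edge_um <= 0:
            raise ValueError("voxel_edge_um must be positive")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        object.__setattr__(self, "side_lengths", tuple(int(s) for s in self.side_lengths))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.side_lengths
        return nx * ny * nz

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * (self.voxel_edge_um / 1000.0) ** 3

    def contains(self, pos: tuple[int, int, int]) -> bool:
        return all(0 <= p < s for p, s in zip(pos, self.side_lengths))

    def flat_index(self, pos: tuple[int, int, int]) -> int:
        x, y, z = pos
        nx, ny, _ = self.side_lengths
        return (z * ny + y) * nx + x

    def unflat(self, idx: int) -> tuple[int, int, int]:
        nx, ny, _ = self.side_lengths
        return (idx % nx, (idx // nx) % ny, idx // (nx * ny))

    def is_border(self, pos: tuple[int, int, int]) -> bool:
        return any(p == 0 or p == s - 1 for p, s in zip(pos, self.side_lengths))


@dataclass
class ModelParameters:
    """All behavioral parameters of the agent rules.

    Probabilities are per 10-min step, durations in steps, secretion rates in
    concentration units per minute per voxel, tau rate constants per
    concentration unit.  ``g`` is the checkpoint-therapy exponent applied to
    the kill probability (1 = no therapy, 0.1 = anti-PD1 applied).

    Nominal values follow the full-scale 100-day configuration; see
    docs/methods.md for the calibration rationale.
    """

    # cancer cells
    p_migration_cancer: float = 0.1
    p_death: float = 5e-4
    p_mutation: float = 1e-3
    t_proliferation: int = 144          # 24 h cell cycle
    # CTLs
    p_base: float = 0.1
    t_kill: int = 6                     # 1 h kill handling time
    t_life_ctl: int = 432               # 3 days in the TME
    enh_chemotaxis_threshold: float = 0.3
    # accessory cells
    t_life_helper: int = 288
    t_life_suppressor: int = 288
    t_life_macrophage: int = 576
    p_base_macrophage: float = 0.05
    # cytokine couplings
    tau_enh: float = 0.5
    tau_sup: float = 0.5
    r_enh: float = 0.2                  # conc units / min secreted at the cell's voxel
    r_cytokine: float = 0.2             # total macrophage secretion budget, conc/min
    # recruitment
    t_delay: int = 432                  # lymph-node delay, steps
    r_ctl: float = 3.0                  # CTLs recruited per unit of emitted DC signal
    q_macrophage: float = 0.2
    q_suppressor: float = 0.2
    recruitment_scale: float = 1.0      # 1/3 models the low-infiltration scenario
    # immune motility (immune cells attempt a move every step)
    p_migration_immune: float = 1.0
    # therapy
    g: float = 0.1
    # population setup / termination
    n_antigens: int = N_ANTIGENS
    initial_cancer_cells: int = 125
    initial_dcs: int = 500
    initial_macrophages: int = 500
    abort_threshold: int = 800_000

    #: parameters eligible for the +/-25% patient-diversity perturbation and
    #: for the (0, 2)x nominal global sensitivity bounds.
    PERTURBABLE = (
        "p_migration_cancer", "p_death", "p_mutation", "t_proliferation",
        "p_base", "t_kill", "t_life_ctl", "enh_chemotaxis_threshold",
        "t_life_helper", "t_life_suppressor", "t_life_macrophage",
        "p_base_macrophage", "tau_enh", "tau_sup", "r_enh", "r_cytokine",
        "t_delay", "r_ctl", "q_macrophage", "q_suppressor",
    )
    _DURATION_FIELDS = (
        "t_proliferation", "t_kill", "t_life_ctl", "t_life_helper",
        "t_life_suppressor", "t_life_macrophage", "t_delay",
    )

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("p_migration_cancer", "p_death", "p_mutation", "p_base",
                     "p_base_macrophage", "p_migration_immune"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        for name in self._DURATION_FIELDS:
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name}={v} must be >= 1 step")
            setattr(self, name, int(round(v)))
        for name in ("tau_enh", "tau_sup", "r_enh", "r_cytokine", "r_ctl",
                     "q_macrophage", "q_suppressor", "recruitment_scale",
                     "enh_chemotaxis_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.g <= 1.0:
            raise ValueError("g must be in (0, 1]")
        if self.n_antigens != N_ANTIGENS:
            raise ValueError(f"n_antigens is fixed at {N_ANTIGENS}")

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class AntigenGenotype:
    """Set of presented tumor antigens under the 32-allele model.

    Internally a bitmask over indices 0..31; cancer cells always present at
    least one antigen.
    """

    mask: int = 1  # baseline antigen index 0

    def __post_init__(self):
        if not 0 <= self.mask < (1 << N_ANTIGENS):
            raise ValueError("antigen mask out of range")

    @classmethod
    def from_antigens(cls, antigens: Iterable[int]) -> "AntigenGenotype":
        mask = 0
        for a in antigens:
            if not 0 <= a < N_ANTIGENS:
                raise ValueError(f"antigen index {a} outside 0..{N_ANTIGENS - 1}")
            mask |= 1 << a
        return cls(mask)

    @property
    def antigens(self) -> frozenset[int]:
        return frozenset(i for i in range(N_ANTIGENS) if self.mask >> i & 1)

    def presents(self, antigen: int) -> bool:
        return bool(self.mask >> antigen & 1)

    def __len__(self) -> int:
        return int(self.mask).bit_count()


@dataclass
class CellRecord:
    """Snapshot of one agent, used at the Python API surface (the engine keeps
    agents in structure-of-arrays form)."""

    kind: str
    position: tuple[int, int, int]
    genotype: Optional[AntigenGenotype] = None
    specificity: int = -1
    age: int = 0
    immobile_until: int = 0
    activated: bool = False
    proliferation_timer: int = 0


def moore_neighborhood(pos: tuple[int, int, int], lattice: LatticeConfig) -> list[tuple[int, int, int]]:
    """In-bounds voxels at Chebyshev distance 1 from ``pos`` (no wraparound)."""
    if not lattice.contains(pos):
        raise ValueError(f"position {pos} outside lattice {lattice.side_lengths}")
    x, y, z = pos
    nx, ny, nz = lattice.side_lengths
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                xx, yy, zz = x + dx, y + dy, z + dz
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    out.append((xx, yy, zz))
    return out


def attempt_move(pos, p_move, occupied, lattice, rng):
    """Random-walk move attempt with the swap rule.

    With probability ``p_move`` a uniformly random Moore neighbor is targeted;
    a vacant target is taken, an occupied one leads to a position swap with
    probability 1/2 (otherwise both cells stay).

    Parameters
    ----------
    occupied : set-like of positions currently holding a cell.

    Returns ``(new_pos, partner_move)`` where ``partner_move`` is
    ``(partner_old, partner_new)`` when a swap happened, else ``None``.
    """
    if rng.random() >= p_move:
        return pos, None
    nbrs = moore_neighborhood(pos, lattice)
    if not nbrs:
        return pos, None
    target = nbrs[rng.integers(len(nbrs))]
    if target not in occupied:
        return target, None
    if rng.random() < 0.5:
        return target, (target, pos)
    return pos, None


# ---------------------------------------------------------------------------
# JSON (de)serialization of configurations


def _config_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def params_to_json(params: ModelParameters) -> str:
    return json.dumps(_config_to_dict(params), indent=2, sort_keys=True)


def params_from_dict(d: dict) -> ModelParameters:
    return ModelParameters(**d)
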