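"""Antigen-specific delayed CTL recruitment and ratio-coupled accessory
recruitment at the lattice border.

DCs leaving the TME push recruitment signal onto per-antigen FIFO queues of
fixed length ``t_delay`` (the implicit lymph-node compartment).  Each step the
oldest slot is dequeued and converted into border recruits: CTLs at rate
``r_ctl`` per signal unit (antigen-specific), helpers 1:1 with CTLs, and
macrophages/suppressors at fixed ratios ``q_<celltype>`` of the CTL count.
Fractional counts are rounded probabilistically (floor + Bernoulli on the
fractional part), which is unbiased in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .model_core import N_ANTIGENS
from .state import SimulationState


@dataclass
class RecruitmentRates:
    """Recruitment coupling constants; helpers are fixed at 1:1 with CTLs."""

    r_ctl: float = 3.0
    helper_ratio: float = 1.0
    q_macrophage: float = 0.2
    q_suppressor: float = 0.2
    recruitment_scale: float = 1.0

    def __post_init__(self):
        if min(self.r_ctl, self.q_macrophage, self.q_suppressor,
               self.recruitment_scale) < 0:
            raise ValueError("recruitment rates must be >= 0")


class AntigenDelayQueues:
    """Per-antigen FIFO of signal magnitudes with fixed length ``t_delay``.

    ``push`` adds to the newest slot; ``advance`` dequeues the oldest slot of
    every antigen and enqueues zeros, so a signal pushed at step t emerges at
    step t + t_delay, exactly once.
    """

    def __init__(self, t_delay: int):
        if t_delay < 1:
            raise ValueError("t_delay must be >= 1 step")
        self.t_delay = int(t_delay)
        self.data = np.zeros((self.t_delay, N_ANTIGENS))
        self.head = 0  # oldest slot

    def push(self, antigen: int, amount: float) -> None:
        if not 0 <= antigen < N_ANTIGENS:
            raise ValueError(f"antigen index {antigen} outside 0..{N_ANTIGENS - 1}")
        if amount < 0:
            raise ValueError("signal amount must be >= 0")
        newest = (self.head + self.t_delay - 1) % self.t_delay
        self.data[newest, antigen] += amount

    def advance(self) -> np.ndarray:
        emitted = self.data[self.head].copy()
        self.data[self.head] = 0.0
        self.head = (self.head + 1) % self.t_delay
        return emitted

    def total_pending(self) -> float:
        return float(self.data.sum())


def push_dc_signal(queues: AntigenDelayQueues, antigen: int, amount: float) -> AntigenDelayQueues:
    """Increment the newest slot of one antigen's queue by ``amount``."""
    queues.push(antigen, amount)
    return queues


def advance_delay_queues(queues: AntigenDelayQueues):
    """Dequeue the oldest per-antigen signal; returns (queues, emitted)."""
    return queues, queues.advance()


def spawn_recruits(state: SimulationState, emitted: np.ndarray,
                   rates: RecruitmentRates, seed: int | None = None) -> dict[str, int]:
    """Place recruits for one step of emitted signal at free border voxels.

    Returns the per-kind counts actually placed; surplus recruits for which no
    free border voxel was found are dropped and counted in the engine meta.
    """
    if seed is not None:
        _k.seed_rng(seed)
    if (np.asarray(emitted) < 0).any():
        raise ValueError("emitted signal must be >= 0")
    fp = np.zeros(_k.N_FP)
    fp[_k.FP_R_CTL] = rates.r_ctl
    fp[_k.FP_Q_MACRO] = rates.q_macrophage
    fp[_k.FP_Q_SUPP] = rates.q_suppressor
    fp[_k.FP_RECRUIT_SCALE] = rates.recruitment_scale
    nx, ny, nz = state.lattice.side_lengths
    before = state.counts()
    _k.spawn_recruits(state.step, np.asarray(emitted, dtype=np.float64),
                      state.occ, state.kind, state.pos, state.geno, state.spec,
                      state.age, state.immobile, state.prolif, state.activated,
                      state.alive, state.born, state.free_stack, state.meta,
                      fp, nx, ny, nz)
    after = state.counts()
    return {k: after[k] - before[k] for k in after}
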