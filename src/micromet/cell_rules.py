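"""Per-step behavioral rules for each cell type.

The rules themselves live in the numba kernels (one implementation shared
with the engine); this module provides the closed-form pieces (kill
probability, macrophage secretion shares) in plain Python and thin wrappers
that apply one agent's rule to a :class:`~micromet.state.SimulationState`.

Kernel-backed wrappers draw randomness from the kernel RNG; pass ``seed`` to
make a call reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .model_core import AntigenGenotype, ModelParameters
from .state import SimulationState


@dataclass(frozen=True)
class KillContext:
    """Inputs of one kill attempt: base probability, cytokine couplings, local
    concentrations at the killer's voxel, and the therapy exponent g."""

    p_base: float
    tau_enh: float
    tau_sup: float
    enh_local: float
    sup_local: float
    g: float = 1.0

    def __post_init__(self):
        if not 0 <= self.p_base <= 1:
            raise ValueError("p_base must be a probability")
        if min(self.tau_enh, self.tau_sup, self.enh_local, self.sup_local) < 0:
            raise ValueError("rate constants and concentrations must be >= 0")
        if not 0 < self.g <= 1:
            raise ValueError("g must be in (0, 1]")


def compute_pkill(ctx: KillContext) -> float:
    """Kill probability of a cytotoxic cell in contact with a recognized
    cancer cell::

        p_kill = (p_base + (1 - p_base) * (1 - exp(-tau_ENH*[ENH]))
                                        * exp(-tau_SUP*[SUP])) ** g

    ENH boosts, SUP damps the enhancement term; checkpoint therapy acts as a
    power law (g = 0.1 raises the probability toward 1).
    """
    p = ctx.p_base + (1.0 - ctx.p_base) \
        * (1.0 - math.exp(-ctx.tau_enh * ctx.enh_local)) \
        * math.exp(-ctx.tau_sup * ctx.sup_local)
    return p ** ctx.g


def macrophage_secretion_rates(enh_local: float, sup_local: float,
                               r_cytokine: float) -> tuple[float, float]:
    """Concentration-share secretion of a macrophage: r_ENH and r_SUP are
    proportional to the local ENH/SUP shares and sum exactly to r_cytokine
    (positive feedback imitating M1/M2 plasticity).  At zero concentrations
    the budget is split equally (neutral M0 state)."""
    if min(enh_local, sup_local, r_cytokine) < 0:
        raise ValueError("inputs must be >= 0")
    total = enh_local + sup_local
    if total == 0:
        return r_cytokine / 2.0, r_cytokine / 2.0
    share = enh_local / total
    return share * r_cytokine, (1.0 - share) * r_cytokine


def mutate_genotype(genotype: AntigenGenotype, p_mutation: float,
                    seed: int | None = None) -> AntigenGenotype:
    """With probability ``p_mutation`` toggle one uniformly chosen allele of
    the 32 (reverse mutations allowed); a toggle that would empty the antigen
    set is redrawn, so cancer cells always present at least one antigen."""
    if seed is not None:
        _k.seed_rng(seed)
    return AntigenGenotype(int(_k.mutate_mask(genotype.mask, p_mutation)))


# ---------------------------------------------------------------------------
# kernel-backed per-agent rule wrappers

def _kernel_args(state: SimulationState):
    nx, ny, nz = state.lattice.side_lengths
    return (state.occ, state.debris, state.kind, state.pos, state.geno,
            state.spec, state.age, state.immobile, state.prolif,
            state.activated, state.alive, state.born, state.free_stack,
            state.meta), (nx, ny, nz)


def pack_params(params: ModelParameters, dt_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Pack ModelParameters into the kernel float/int parameter vectors."""
    fp = np.zeros(_k.N_FP)
    fp[_k.FP_PMIG_CANCER] = params.p_migration_cancer
    fp[_k.FP_PMIG_IMMUNE] = params.p_migration_immune
    fp[_k.FP_PDEATH] = params.p_death
    fp[_k.FP_PMUT] = params.p_mutation
    fp[_k.FP_PBASE] = params.p_base
    fp[_k.FP_PBASE_MACRO] = params.p_base_macrophage
    fp[_k.FP_TAU_ENH] = params.tau_enh
    fp[_k.FP_TAU_SUP] = params.tau_sup
    fp[_k.FP_R_ENH] = params.r_enh
    fp[_k.FP_R_CYT] = params.r_cytokine
    fp[_k.FP_R_CTL] = params.r_ctl
    fp[_k.FP_Q_MACRO] = params.q_macrophage
    fp[_k.FP_Q_SUPP] = params.q_suppressor
    fp[_k.FP_CHEMO_T] = params.enh_chemotaxis_threshold
    fp[_k.FP_DT_MIN] = dt_min
    fp[_k.FP_RECRUIT_SCALE] = params.recruitment_scale
    ip = np.zeros(_k.N_IP, dtype=np.int64)
    ip[_k.IP_TPROLIF] = params.t_proliferation
    ip[_k.IP_TKILL] = params.t_kill
    ip[_k.IP_TLIFE_CTL] = params.t_life_ctl
    ip[_k.IP_TLIFE_HELPER] = params.t_life_helper
    ip[_k.IP_TLIFE_SUPP] = params.t_life_suppressor
    ip[_k.IP_TLIFE_MACRO] = params.t_life_macrophage
    ip[_k.IP_TDELAY] = params.t_delay
    return fp, ip


_EVENTS = {0: "none", 1: "died", 2: "engaged", 3: "killed"}
_CANCER_EVENTS = {0: "none", 1: "died", 2: "divided"}


def cancer_cell_update(state: SimulationState, i: int, seed: int | None = None) -> str:
    """Apply one cancer-cell step (death -> debris, mutation, division,
    migration) to agent ``i`` in place; returns the event name."""
    if seed is not None:
        _k.seed_rng(seed)
    arrays, dims = _kernel_args(state)
    fp, ip = pack_params(state.params, state.lattice.dt_min)
    ev = _k.cancer_step(i, state.step, *arrays, fp, ip, *dims, state._nbuf)
    return _CANCER_EVENTS[int(ev)]


def ctl_update(state: SimulationState, i: int, g: float | None = None,
               seed: int | None = None) -> str:
    """Apply one CTL step (expiry, antigen-specific kill, chemotactic or
    random migration) to agent ``i``; returns the event name."""
    if seed is not None:
        _k.seed_rng(seed)
    arrays, dims = _kernel_args(state)
    fp, ip = pack_params(state.params, state.lattice.dt_min)
    g_eff = 1.0 if g is None else g
    ev = _k.ctl_step(i, state.step, *arrays, state.enh, state.sup, fp, ip,
                     g_eff, *dims, state._nbuf, state._obuf)
    return {0: "moved", 1: "expired", 2: "engaged", 3: "killed"}[int(ev)]


def dc_update(state: SimulationState, i: int, seed: int | None = None) -> str:
    """Apply one DC step (debris collection, departure + recruitment signal +
    border respawn, else move); returns the event name."""
    if seed is not None:
        _k.seed_rng(seed)
    arrays, dims = _kernel_args(state)
    fp, ip = pack_params(state.params, state.lattice.dt_min)
    ev = _k.dc_step(i, state.step, *arrays, state.queues, fp, ip, *dims,
                    state._nbuf)
    return {0: "moved", 1: "left"}[int(ev)]


def accessory_cell_update(state: SimulationState, i: int, g: float = 1.0,
                          seed: int | None = None) -> str:
    """Apply one helper/suppressor/macrophage step; returns the event name."""
    if seed is not None:
        _k.seed_rng(seed)
    arrays, dims = _kernel_args(state)
    fp, ip = pack_params(state.params, state.lattice.dt_min)
    ev = _k.accessory_step(i, state.step, *arrays, state.enh, state.sup,
                           fp, ip, g, *dims, state._nbuf, state._obuf)
    return {0: "moved", 1: "expired", 2: "engaged", 3: "killed"}[int(ev)]
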