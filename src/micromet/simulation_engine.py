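"""Step scheduler, therapy toggling, termination, outcome classification and
replication management.

Per step the engine (1) deposits secretion, (2) runs the explicit diffusion
substeps, (3) advances the recruitment delay queues and spawns border
recruits, (4) updates all agents in a uniformly re-shuffled order, then
applies the abort rule (cancer population above ``abort_threshold`` ends the
run early, simulating expansion beyond the model space).  Therapy switches
the kill-probability exponent g from 1 to its configured value (0.1) at
``therapy_start_step``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels as _k
from .cell_rules import pack_params
from .cytokine_diffusion import DiffusionParams, _validate_substep
from .model_core import LatticeConfig, ModelParameters, _config_to_dict
from .state import SimulationState, build_initial_state


logger = logging.getLogger("micromet")


class Outcome(str, enum.Enum):
    COMPLETE_REMISSION = "complete_remission"
    RESIDUAL_DISEASE = "residual_disease"
    EMERGING_METASTASIS = "emerging_metastasis"


@dataclass(frozen=True)
class OutcomeLabel:
    label: Outcome
    final_cancer_count: int


@dataclass
class SimulationConfig:
    """Complete specification of one simulation run."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    params: ModelParameters = field(default_factory=ModelParameters)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    duration_days: float = 100.0
    duration_steps: Optional[int] = None     # overrides duration_days if set
    therapy_start_step: Optional[int] = None
    metastasis_threshold: int = 700_000
    snapshot_interval: int = 0               # 0 = no field snapshots
    perturbation_fraction: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        n = self.total_steps
        if n < 1:
            raise ValueError("simulation must have at least one step")
        if self.therapy_start_step is not None and not 0 <= self.therapy_start_step < n:
            raise ValueError("therapy_start_step must lie within the run")
        if self.metastasis_threshold < 0:
            raise ValueError("metastasis_threshold must be >= 0")

    @property
    def total_steps(self) -> int:
        if self.duration_steps is not None:
            return int(self.duration_steps)
        return int(round(self.duration_days * 1440.0 / self.lattice.dt_min))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return _config_to_dict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        lat = dict(d.pop("lattice", {}))
        if "side_lengths" in lat:
            lat["side_lengths"] = tuple(lat["side_lengths"])
        return cls(lattice=LatticeConfig(**lat),
                   params=ModelParameters(**d.pop("params", {})),
                   diffusion=DiffusionParams(**d.pop("diffusion", {})),
                   **d)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def classify_outcome(final_cancer_count: int,
                     metastasis_threshold: int = 700_000) -> OutcomeLabel:
    """0 -> complete remission; > threshold -> emerging metastasis; else
    residual disease."""
    if final_cancer_count < 0:
        raise ValueError("cancer count must be >= 0")
    if final_cancer_count == 0:
        label = Outcome.COMPLETE_REMISSION
    elif final_cancer_count > metastasis_threshold:
        label = Outcome.EMERGING_METASTASIS
    else:
        label = Outcome.RESIDUAL_DISEASE
    return OutcomeLabel(label, int(final_cancer_count))


def run_simulation(config: SimulationConfig, seed: int,
                   return_state: bool = False):
    """Run one replica; returns ``(time_series, outcome)`` (plus the final
    state when ``return_state``).

    The time series is a DataFrame with per-step population counts, total
    cytokine masses, cumulative kills and the therapy flag.  A fixed seed
    yields a bit-identical trajectory.
    """
    config.validate()
    lattice = config.lattice
    params = config.params
    rng = np.random.default_rng(seed)
    state = build_initial_state(config, rng)
    state.seed_kernel_rng(seed + 1)
    fp, ip = pack_params(params, lattice.dt_min)
    dt_sub, n_sub = _validate_substep(config.diffusion, lattice)
    nx, ny, nz = lattice.side_lengths
    n_steps = config.total_steps

    rows = np.zeros((n_steps, 11))
    cancer_count = state.cancer_count()
    aborted = False
    state.snapshots = []  # (step, enh, sup) field snapshots
    for step in range(n_steps):
        state.step = step
        g = 1.0
        if config.therapy_start_step is not None and step >= config.therapy_start_step:
            g = params.g
        cancer_count = int(_k.sim_step(
            step, state.occ, state.debris, state.kind, state.pos, state.geno,
            state.spec, state.age, state.immobile, state.prolif,
            state.activated, state.alive, state.born, state.free_stack,
            state.meta, state.enh, state.sup, state.queues, state._emitted,
            fp, ip, g,
            config.diffusion.d_enh, config.diffusion.d_sup,
            config.diffusion.lambda_decay, config.diffusion.lambda_decay,
            dt_sub, n_sub, lattice.voxel_edge_um,
            nx, ny, nz, state._tmp, state._nbuf, state._obuf, state._ids))
        if config.snapshot_interval and step % config.snapshot_interval == 0:
            state.snapshots.append((step, state.enh.reshape(nz, ny, nx).copy(),
                                    state.sup.reshape(nz, ny, nx).copy()))
        c = np.bincount(state.kind[state.alive], minlength=7)
        rows[step] = (step, c[1], c[2], c[3], c[4], c[5], c[6],
                      state.enh.sum(), state.sup.sum(),
                      state.meta[_k.M_KILLS], 1.0 if g < 1.0 else 0.0)
        if step and step % 1000 == 0:
            logger.debug("step %d: %d cancer cells", step, cancer_count)
        if cancer_count > params.abort_threshold:
            aborted = True
            rows = rows[: step + 1]
            logger.info("abort at step %d: cancer population %d exceeds %d",
                        step, cancer_count, params.abort_threshold)
            break
        if cancer_count == 0:
            # extinction is absorbing for the outcome: no cancer cells means
            # no divisions and no further debris, so the run ends here
            rows = rows[: step + 1]
            break

    ts = pd.DataFrame(rows, columns=[
        "step", "cancer", "ctl", "dc", "macrophage", "helper", "suppressor",
        "enh_total", "sup_total", "cum_kills", "therapy"])
    ts = ts.astype({"step": int, "cancer": int, "ctl": int, "dc": int,
                    "macrophage": int, "helper": int, "suppressor": int,
                    "cum_kills": int})
    ts.attrs["aborted"] = aborted
    dropped = int(state.meta[_k.M_DROPPED])
    if dropped:
        logger.warning("%d recruits dropped (no free border voxel)", dropped)
    outcome = classify_outcome(cancer_count, config.metastasis_threshold)
    if return_state:
        return ts, outcome, state
    return ts, outcome


_PROB_FIELDS = {"p_migration_cancer", "p_death", "p_mutation", "p_base",
                "p_base_macrophage"}


def perturb_parameters(params: ModelParameters, fraction: float,
                       rng: np.random.Generator) -> ModelParameters:
    """Multiply every perturbable parameter by an independent
    Uniform(1 - fraction, 1 + fraction) factor (patient diversity);
    probabilities are clipped to [0, 1] and durations kept >= 1 step."""
    if fraction < 0:
        raise ValueError("perturbation fraction must be >= 0")
    changes = {}
    for name in ModelParameters.PERTURBABLE:
        factor = rng.uniform(1.0 - fraction, 1.0 + fraction)
        v = getattr(params, name) * factor
        if name in _PROB_FIELDS:
            v = min(1.0, max(0.0, v))
        if name in ModelParameters._DURATION_FIELDS:
            v = max(1, int(round(v)))
        changes[name] = v
    return params.replace(**changes)


def run_replicates(config: SimulationConfig, n_replicates: int,
                   perturbation_fraction: float = 0.0,
                   seed: int = 0) -> list[tuple[pd.DataFrame, OutcomeLabel]]:
    """Run independent replicas (independent seeds; optional parameter
    perturbation per replica) and return their (time_series, outcome) pairs."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    results = []
    for r in range(n_replicates):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        cfg = config
        if perturbation_fraction > 0:
            cfg = config.replace(params=perturb_parameters(
                config.params, perturbation_fraction, rng))
        results.append(run_simulation(cfg, rep_seed))
    return results


def tally_outcomes(results) -> dict[str, int]:
    tally = {o.value: 0 for o in Outcome}
    for _, outcome in results:
        tally[outcome.label.value] += 1
    return tally


def remission_fraction(results) -> float:
    n = len(results)
    return sum(1 for _, o in results
               if o.label is Outcome.COMPLETE_REMISSION) / n if n else float("nan")


def paired_outcome_experiment(config_a: SimulationConfig,
                              config_b: SimulationConfig,
                              n_pairs: int, seed: int = 0,
                              perturbation_fraction: float = 0.0):
    """Run the two configurations on shared seeds (paired design).

    Returns ``(outcomes_a, outcomes_b)`` as lists of OutcomeLabel.  Used for
    the therapy- and infiltration-monotonicity experiments.
    """
    rng = np.random.default_rng(seed)
    out_a, out_b = [], []
    for _ in range(n_pairs):
        s = int(rng.integers(0, 2 ** 31 - 1))
        cfg_a, cfg_b = config_a, config_b
        if perturbation_fraction > 0:
            pa = perturb_parameters(config_a.params, perturbation_fraction,
                                    np.random.default_rng(s + 7))
            # apply the same multiplicative draws to both arms
            pb = config_b.params
            for name in ModelParameters.PERTURBABLE:
                ratio = getattr(pa, name) / max(getattr(config_a.params, name), 1e-300)
                v = getattr(config_b.params, name) * ratio
                if name in _PROB_FIELDS:
                    v = min(1.0, max(0.0, v))
                if name in ModelParameters._DURATION_FIELDS:
                    v = max(1, int(round(v)))
                pb = pb.replace(**{name: v})
            cfg_a = config_a.replace(params=pa)
            cfg_b = config_b.replace(params=pb)
        out_a.append(run_simulation(cfg_a, s)[1])
        out_b.append(run_simulation(cfg_b, s)[1])
    return out_a, out_b


def save_run_h5(path, ts: pd.DataFrame, outcome: OutcomeLabel,
                config: SimulationConfig, state: SimulationState | None = None) -> None:
    """Write a run to HDF5: the per-step time series, outcome, resolved
    config (JSON attribute) and optional final cytokine field snapshots."""
    import h5py

    with h5py.File(path, "w") as h5:
        grp = h5.create_group("timeseries")
        for col in ts.columns:
            grp.create_dataset(col, data=ts[col].to_numpy())
        h5.attrs["outcome"] = outcome.label.value
        h5.attrs["final_cancer_count"] = outcome.final_cancer_count
        h5.attrs["config_json"] = config.to_json()
        if state is not None:
            nx, ny, nz = config.lattice.side_lengths
            h5.create_dataset("fields/enh", data=state.enh.reshape(nz, ny, nx))
            h5.create_dataset("fields/sup", data=state.sup.reshape(nz, ny, nx))
            for step, enh, sup in getattr(state, "snapshots", []):
                h5.create_dataset(f"snapshots/{step}/enh", data=enh)
                h5.create_dataset(f"snapshots/{step}/sup", data=sup)
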