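"""Canonical desk-scale experiments on the scaled profile.

These are the paired study designs used to probe the model's qualitative
behavior: checkpoint therapy (g: 1 -> 0.1) should not decrease the
complete-remission fraction, and 3-fold reduced immune-cell recruitment
(the low-infiltration scenario) should not increase it.
"""

from __future__ import annotations

from .simulation_engine import (
    Outcome, SimulationConfig, paired_outcome_experiment, remission_fraction,
)
from .synthetic_data import generate_toy_scenario


def therapy_arms() -> tuple[SimulationConfig, SimulationConfig]:
    """(no therapy, anti-PD1 from step 0) on the scaled profile."""
    base = generate_toy_scenario("scaled")
    return base, base.replace(therapy_start_step=0)


def infiltration_arms() -> tuple[SimulationConfig, SimulationConfig]:
    """(nominal recruitment, 3-fold reduced recruitment), both treated."""
    treated = generate_toy_scenario("scaled").replace(therapy_start_step=0)
    low = treated.replace(params=treated.params.replace(
        recruitment_scale=1.0 / 3.0))
    return treated, low


def _fractions(pairs):
    out_a, out_b = pairs
    return {
        "fraction_a": remission_fraction([(None, o) for o in out_a]),
        "fraction_b": remission_fraction([(None, o) for o in out_b]),
        "outcomes_a": [o.label.value for o in out_a],
        "outcomes_b": [o.label.value for o in out_b],
    }


def therapy_monotonicity_experiment(n_pairs: int = 30, seed: int = 0) -> dict:
    """Paired seeds, no-therapy vs therapy; returns remission fractions
    (a = untreated, b = treated)."""
    cfg_a, cfg_b = therapy_arms()
    return _fractions(paired_outcome_experiment(cfg_a, cfg_b, n_pairs, seed))


def infiltration_monotonicity_experiment(n_pairs: int = 30, seed: int = 0) -> dict:
    """Paired seeds, nominal vs 3-fold reduced recruitment under therapy;
    returns remission fractions (a = nominal, b = low infiltration)."""
    cfg_a, cfg_b = infiltration_arms()
    return _fractions(paired_outcome_experiment(cfg_a, cfg_b, n_pairs, seed))
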