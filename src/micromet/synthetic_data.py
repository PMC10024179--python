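"""Generators for every pipeline input that would otherwise require
downloads: expression matrices emulating the responder / non-responder
structure of pre-treatment anti-PD1 melanoma cohorts, GMT gene-set
collections, and small simulation scenarios.

All generators are pure functions of their spec plus seed, and return truth
tables so downstream power and calibration claims are testable without
external data.  The expression model is Gaussian noise on log2 scale
(log-normal expression); platform quirks of real cohort data (batch effects,
FPKM zero-inflation) are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytokine_diffusion import DiffusionParams
from .model_core import LatticeConfig, ModelParameters
from .simulation_engine import SimulationConfig
from .transcriptomics_link import NON_RESPONDER, RESPONDER, default_annotation


@dataclass
class ExpressionSimSpec:
    """Specification of one synthetic two-group expression dataset.

    ``planted_sets`` maps set name -> (size, mean log2 shift); planted genes
    are disjoint across sets.  Responders receive the positive shift by
    convention, so planted enrichment signs are predictable.
    """

    n_genes: int = 4000
    n_responders: int = 15           # cohort shape of the emulated study
    n_non_responders: int = 13
    planted_sets: dict[str, tuple[int, float]] = field(default_factory=dict)
    noise_sd: float = 0.5            # log2 units
    baseline_mean: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if sum(size for size, _ in self.planted_sets.values()) > self.n_genes:
            raise ValueError("planted sets exceed the gene universe")
        if min(self.n_responders, self.n_non_responders) < 2:
            raise ValueError("need >= 2 samples per group")


def generate_expression_dataset(spec: ExpressionSimSpec):
    """Synthesize (expression genes x samples, labels, truth table).

    Every gene gets i.i.d. Gaussian log2 noise; genes of a planted set with
    shift delta have responder-group means higher by delta.  The truth table
    records gene, set and shift for every planted gene.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    samples = [f"R{i:02d}" for i in range(spec.n_responders)] + \
              [f"N{i:02d}" for i in range(spec.n_non_responders)]
    labels = pd.Series([RESPONDER] * spec.n_responders
                       + [NON_RESPONDER] * spec.n_non_responders,
                       index=samples, name="group")
    x = rng.normal(spec.baseline_mean, spec.noise_sd,
                   size=(spec.n_genes, len(samples)))
    truth_rows = []
    cursor = 0
    for set_name, (size, delta) in spec.planted_sets.items():
        idx = np.arange(cursor, cursor + size)
        cursor += size
        x[np.ix_(idx, np.arange(spec.n_responders))] += delta
        for i in idx:
            truth_rows.append({"gene": genes[i], "set": set_name, "shift": delta})
    expr = pd.DataFrame(x, index=genes, columns=samples)
    truth = pd.DataFrame(truth_rows, columns=["gene", "set", "shift"])
    return expr, labels, truth


def generate_gene_set_collection(n_sets: int, size_range: tuple[int, int],
                                 n_genes: int, seed: int = 0,
                                 genes: list[str] | None = None,
                                 names: list[str] | None = None) -> dict[str, list[str]]:
    """Random gene sets with unique names over a gene universe (GMT-ready)."""
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if not 1 <= lo <= hi <= n_genes:
        raise ValueError("infeasible size range")
    universe = genes if genes is not None else [f"G{i:05d}" for i in range(n_genes)]
    if names is None:
        names = [f"random_set_{i:03d}" for i in range(n_sets)]
    if len(names) != n_sets or len(set(names)) != n_sets:
        raise ValueError("need n_sets unique names")
    out = {}
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        out[name] = list(rng.choice(universe, size=size, replace=False))
    return out


#: the 14 significantly enriched but unmapped sets of the emulated study
#: (generic, disease-specific or unmodeled processes; three metabolic sets
#: among them are natural model-expansion candidates).
UNMAPPED_SET_NAMES = [
    "oxidative_phosphorylation", "glycolysis", "fatty_acid_metabolism",
    "apoptosis", "hypoxia", "p53_pathway", "myc_targets", "complement",
    "coagulation", "angiogenesis", "adipogenesis", "uv_response",
    "xenobiotic_metabolism", "kras_signaling",
]


def generate_linked_scenario(seed: int = 0, set_size: int = 50,
                             shift: float = 1.5, noise_sd: float = 0.5,
                             n_genes: int = 8000, n_null_sets: int = 20):
    """Full synthetic linkage study: expression with signal planted in the 10
    annotated sets (mapping to 6 model parameters) and in 14 unmapped sets,
    plus unshifted decoy sets.

    Returns ``(expr, labels, sets, annotation, truth)``.
    """
    annotation = default_annotation()
    mapped_names = list(annotation)
    planted_names = mapped_names + UNMAPPED_SET_NAMES
    spec = ExpressionSimSpec(
        n_genes=n_genes,
        planted_sets={name: (set_size, shift) for name in planted_names},
        noise_sd=noise_sd, seed=seed)
    expr, labels, truth = generate_expression_dataset(spec)
    sets = {name: truth.loc[truth["set"] == name, "gene"].tolist()
            for name in planted_names}
    # unshifted decoys drawn from the non-planted tail of the universe
    n_planted = len(planted_names) * set_size
    tail = list(expr.index[n_planted:])
    decoys = generate_gene_set_collection(
        n_null_sets, (set_size // 2, set_size * 2), len(tail), seed=seed + 1,
        genes=tail)
    sets.update(decoys)
    return expr, labels, sets, annotation, truth


# ---------------------------------------------------------------------------
# simulation scenarios

def generate_toy_scenario(profile: str = "scaled") -> SimulationConfig:
    """Desk-scale simulation configurations.

    - ``minimal``: 10^3 lattice, no immune cells, growth only (oracle tests).
    - ``scaled``: 30^3 lattice, 2,000 steps, full immune complement, with the
      model's time constants shortened so the growth / surveillance /
      response phases fit the shorter run (see docs/methods.md).
    - ``aggressive``: scaled with halved cell-cycle time and raised motility
      (the resistant phenotype: short replication time, moderate motility).
    - ``full``: the nominal 100-day, 100^3 configuration.
    """
    if profile == "full":
        return SimulationConfig()
    if profile == "minimal":
        return SimulationConfig(
            lattice=LatticeConfig(side_lengths=(10, 10, 10)),
            params=ModelParameters(
                initial_cancer_cells=27, initial_dcs=0, initial_macrophages=0,
                t_proliferation=40, abort_threshold=800),
            duration_steps=400, metastasis_threshold=700)
    scaled = SimulationConfig(
        lattice=LatticeConfig(side_lengths=(30, 30, 30)),
        params=ModelParameters(
            initial_cancer_cells=27, initial_dcs=30, initial_macrophages=20,
            t_proliferation=60, t_delay=120, t_kill=3,
            t_life_ctl=300, t_life_helper=200, t_life_suppressor=200,
            t_life_macrophage=400, p_death=1e-3, r_ctl=1.5,
            abort_threshold=21_600),       # 80% of 27,000 sites
        duration_steps=2000,
        metastasis_threshold=18_900)        # 70% of 27,000 sites
    if profile == "scaled":
        return scaled
    if profile == "aggressive":
        return scaled.replace(params=scaled.params.replace(
            t_proliferation=30, p_migration_cancer=0.2))
    raise ValueError(f"unknown profile {profile!r}")
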