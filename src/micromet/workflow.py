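"""End-to-end workflow: expression data -> parameter shortlist -> Sobol
design -> simulation batch -> sensitivity report, with a reproducibility
manifest.

The shortlist is capped at ``k_max`` parameters (the affordable size of the
global sensitivity analysis); by default the excess parameter with the
largest best adjusted p-value is dropped, optionally replaced by a local
one-at-a-time screen.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .model_core import ModelParameters
from .sensitivity_analysis import (
    SobolDesign, TreeMetamodel, evaluate_design, fit_tree_metamodel,
    local_sensitivity_screen, prcc, resistance_subspaces, sobol_design,
)
from .simulation_engine import SimulationConfig, run_simulation
from .synthetic_data import generate_toy_scenario
from .transcriptomics_link import (
    ParameterShortlist, differential_expression, map_sets_to_parameters,
    preranked_gsea, rank_genes,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_linkage(expr: pd.DataFrame, labels: pd.Series,
                sets: dict[str, list[str]], annotation: dict[str, list[str]],
                alpha: float = 0.05, n_permutations: int = 10_000,
                seed: int = 0):
    """Differential expression -> rank statistic -> preranked GSEA -> BH ->
    parameter mapping.  Returns (enrichment table, ParameterShortlist)."""
    de = differential_expression(expr, labels)
    ranks = rank_genes(de)
    enrichment = preranked_gsea(ranks, sets, n_permutations=n_permutations,
                                seed=seed)
    shortlist = map_sets_to_parameters(enrichment, annotation, alpha=alpha)
    for name in enrichment.index:
        enrichment.loc[name, "linked_parameters"] = ",".join(
            annotation.get(name, []))
    return enrichment, shortlist


def select_parameters(shortlist: ParameterShortlist, k_max: int = 5) -> tuple[list[str], list[str]]:
    """Cap the shortlist at ``k_max`` parameters, keeping the smallest best
    adjusted p-values (ties broken by parameter name).  Returns
    (selected, excluded)."""
    df = shortlist.parameters
    ranked = df.sort_values(["best_p_adjusted"], kind="stable").index.tolist()
    return ranked[:k_max], ranked[k_max:]


def simulation_runner(base_config: SimulationConfig) -> Callable[[dict, int], tuple]:
    """Adapt the ABM engine to the design-evaluation interface: parameter
    overrides are applied to the base configuration's ModelParameters.

    The Sobol design is continuous over (0, 2) x nominal while the model
    quantizes durations to whole steps and caps probabilities at 1, so
    overrides are projected onto the model's admissible space here.
    """

    def run(overrides: dict[str, float], seed: int):
        fixed = {}
        for name, v in overrides.items():
            if name in ModelParameters._DURATION_FIELDS:
                v = max(1, int(round(v)))
            elif name.startswith("p_"):
                v = min(1.0, max(0.0, v))
            fixed[name] = v
        cfg = base_config.replace(
            params=base_config.params.replace(**fixed))
        _, outcome = run_simulation(cfg, seed)
        return outcome.final_cancer_count, outcome.label.value

    return run


@dataclass
class WorkflowReport:
    enrichment: pd.DataFrame
    shortlist: ParameterShortlist
    selected: list[str]
    excluded: list[str]
    design: Optional[SobolDesign]
    outcomes: Optional[pd.DataFrame]
    prcc: Optional[pd.Series]
    tree: Optional[TreeMetamodel]
    resistance: Optional[list]
    manifest: dict


def run_workflow(expr: pd.DataFrame, labels: pd.Series,
                 sets: dict[str, list[str]], annotation: dict[str, list[str]],
                 out_dir, seed: int = 0, alpha: float = 0.05,
                 n_permutations: int = 10_000, k_max: int = 5,
                 levels: int = 5, replicates: int = 3,
                 profile: str = "scaled",
                 base_config: SimulationConfig | None = None,
                 runner: Callable[[dict, int], tuple] | None = None,
                 run_simulations: bool = True) -> WorkflowReport:
    """Chain linkage -> parameter selection -> Sobol design -> simulation
    batch -> PRCC + decision-tree sensitivity report.

    Artifacts (TSV/CSV/JSON) are written to ``out_dir`` together with a
    manifest of digests; ``run_simulations=False`` stops after the design
    (the expensive batch can then be resumed from the cached design).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    try:
        enrichment, shortlist = run_linkage(
            expr, labels, sets, annotation, alpha=alpha,
            n_permutations=n_permutations, seed=seed)
    except Exception as e:  # noqa: BLE001
        raise StageError("linkage", str(e)) from e
    enr_path = out / "enrichment.tsv"
    enrichment.drop(columns=["leading_edge"]).to_csv(enr_path, sep="\t")
    artifacts["enrichment.tsv"] = _sha256(enr_path)

    selected, excluded = select_parameters(shortlist, k_max=k_max)
    sl_path = out / "shortlist.json"
    sl_path.write_text(json.dumps({
        "identified": shortlist.parameters.index.tolist(),
        "selected": selected, "excluded": excluded,
        "expansion_candidates": shortlist.expansion_candidates,
        "alpha": alpha}, indent=2))
    artifacts["shortlist.json"] = _sha256(sl_path)

    design = outcomes = prcc_series = tree = resistance = None
    if selected:
        base = base_config if base_config is not None else generate_toy_scenario(profile)
        nominals = {p: float(getattr(base.params, p)) for p in selected}
        try:
            design = sobol_design(nominals, levels=levels,
                                  replicates=replicates, seed=seed)
        except Exception as e:  # noqa: BLE001
            raise StageError("design", str(e)) from e
        d_path = out / "design.csv"
        design.points.to_csv(d_path, index=False)
        artifacts["design.csv"] = _sha256(d_path)

        if run_simulations:
            try:
                the_runner = runner if runner is not None else simulation_runner(base)
                outcomes = evaluate_design(design, the_runner, seed=seed + 1)
            except Exception as e:  # noqa: BLE001
                raise StageError("simulation_batch", str(e)) from e
            o_path = out / "outcomes.csv"
            outcomes.to_csv(o_path, index=False)
            artifacts["outcomes.csv"] = _sha256(o_path)

            try:
                x = outcomes[selected].to_numpy()
                prcc_series = pd.Series(
                    prcc(x, outcomes["final_cancer_count"].to_numpy()),
                    index=selected, name="prcc")
                tree = fit_tree_metamodel(x, outcomes["label"].tolist(),
                                          feature_names=selected, seed=seed)
                resistance = resistance_subspaces(tree)
            except Exception as e:  # noqa: BLE001
                raise StageError("sensitivity", str(e)) from e
            rep_path = out / "sensitivity_report.json"
            rep_path.write_text(json.dumps({
                "prcc": prcc_series.to_dict(),
                "tree_importance": tree.importances.to_dict(),
                "cv_accuracy_mean": tree.cv_accuracy_mean,
                "cv_accuracy_sd": tree.cv_accuracy_sd,
                "test_accuracy": tree.test_accuracy,
                "resistance_subspaces": [
                    {"constraints": {p: [None if not np.isfinite(lo) else lo,
                                         None if not np.isfinite(hi) else hi]
                                     for p, (lo, hi) in s.constraints.items()},
                     "n_samples": s.n_samples,
                     "sample_fraction": s.sample_fraction}
                    for s in resistance],
            }, indent=2))
            artifacts["sensitivity_report.json"] = _sha256(rep_path)

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "alpha": alpha,
        "n_permutations": n_permutations,
        "k_max": k_max,
        "levels": levels,
        "replicates": replicates,
        "profile": profile,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return WorkflowReport(enrichment, shortlist, selected, excluded, design,
                          outcomes, prcc_series, tree, resistance, manifest)
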