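"""Global sensitivity pipeline: Sobol quasi-Monte-Carlo design over the
shortlisted parameters, outcome labeling of simulation batches, partial rank
correlation coefficients (PRCC), a decision-tree metamodel with feature
importance, and extraction of therapy-resistance parameter subspaces.

The design covers (0, 2) x nominal per parameter with ``levels^k`` scrambled
Sobol points (5 levels for 5 parameters gives 3,125 parameter sets; 3
replicates per set, 9,375 planned runs).  The metamodel is a CART
classification tree (Gini impurity, depth <= 5, minimum split size 3.3% of
the training samples, 80:20 train/test split, 5-fold cross-validation on the
training set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc
from sklearn.model_selection import cross_val_score, train_test_split
from sklearn.tree import DecisionTreeClassifier

#: lower bound of the open interval (0, 2) x nominal, as a fraction of nominal
EPS_LOWER = 1e-9


@dataclass
class SobolDesign:
    parameters: list[str]
    bounds: dict[str, tuple[float, float]]
    points: pd.DataFrame            # n x k, every entry strictly inside bounds
    replicates: int
    seed: int

    @property
    def n_parameter_sets(self) -> int:
        return len(self.points)

    @property
    def planned_runs(self) -> int:
        return self.n_parameter_sets * self.replicates


def sobol_design(nominals: dict[str, float], levels: int = 5,
                 replicates: int = 3, seed: int = 0,
                 scramble: bool = True) -> SobolDesign:
    """Sobol-sequence design of ``levels^k`` points over (0, 2) x nominal.

    The open lower bound is implemented as EPS_LOWER * nominal to avoid
    degenerate zero rates.  Scrambling (Owen) keeps points strictly inside
    the unit cube and is seeded for determinism.
    """
    if not nominals:
        raise ValueError("need at least one parameter")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = list(nominals)
    for p, v in nominals.items():
        if v <= 0:
            raise ValueError(f"nominal for {p!r} must be > 0")
    k = len(params)
    n = levels ** k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two draw
        sampler = qmc.Sobol(d=k, scramble=scramble, seed=seed)
        u = sampler.random(n)
    lo = np.array([EPS_LOWER * nominals[p] for p in params])
    hi = np.array([2.0 * nominals[p] for p in params])
    pts = lo + u * (hi - lo)
    bounds = {p: (float(l), float(h)) for p, l, h in zip(params, lo, hi)}
    return SobolDesign(params, bounds, pd.DataFrame(pts, columns=params),
                       replicates, seed)


def evaluate_design(design: SobolDesign, runner: Callable[[dict[str, float], int], tuple],
                    seed: int = 0) -> pd.DataFrame:
    """Run every design row x replicate through ``runner(overrides, seed) ->
    (final_count, label)``; returns the long-format outcome table."""
    rng = np.random.default_rng(seed)
    rows = []
    for ridx, row in design.points.iterrows():
        overrides = row.to_dict()
        for rep in range(design.replicates):
            s = int(rng.integers(0, 2 ** 31 - 1))
            count, label = runner(overrides, s)
            rows.append({**overrides, "row": ridx, "replicate": rep,
                         "seed": s, "final_cancer_count": count, "label": label})
    return pd.DataFrame(rows)


def prcc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation coefficients.

    Rank-transform design matrix and outcome; for each parameter j correlate
    the residuals of rank(x_j) and rank(y) after linearly removing all other
    rank-transformed parameters.  Reduces to Spearman correlation for k = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = x.shape
    if n <= k + 2:
        raise ValueError("need n > k + 2 samples")
    if (x.std(axis=0) == 0).any():
        raise ValueError("design contains a constant column")
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = stats.rankdata(y)
    out = np.empty(k)
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(rx, j, axis=1)])
        q, _, rank, _ = np.linalg.lstsq(others, np.column_stack([rx[:, j], ry]), rcond=None)
        if rank < others.shape[1]:
            raise ValueError("rank-deficient design")
        res = np.column_stack([rx[:, j], ry]) - others @ q
        sx, sy = res[:, 0].std(), res[:, 1].std()
        out[j] = 0.0 if sx == 0 or sy == 0 else float(np.corrcoef(res[:, 0], res[:, 1])[0, 1])
    return np.clip(out, -1.0, 1.0)


@dataclass
class TreeMetamodel:
    model: DecisionTreeClassifier
    feature_names: list[str]
    importances: pd.Series
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    test_accuracy: float
    classes: list[str]


def fit_tree_metamodel(x: np.ndarray, labels: Sequence[str],
                       feature_names: Sequence[str] | None = None,
                       seed: int = 0, max_depth: int = 5,
                       min_split_fraction: float = 0.033,
                       test_size: float = 0.2) -> TreeMetamodel:
    """CART classification metamodel of the simulation outcome.

    Gini impurity, depth <= ``max_depth``, minimum node size for splitting =
    ``min_split_fraction`` of the training samples; 80:20 train/test split
    and 5-fold CV accuracy on the training set.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if len(x) < 30:
        raise ValueError("need at least 30 samples")
    names = list(feature_names) if feature_names is not None \
        else [f"x{j}" for j in range(x.shape[1])]
    single_class = len(np.unique(labels)) < 2
    if single_class:
        warnings.warn("single-class data: degenerate single-leaf tree")
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, labels, test_size=test_size, random_state=seed)
    else:
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, labels, test_size=test_size, random_state=seed, stratify=labels)
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth,
        min_samples_split=max(2, int(np.ceil(min_split_fraction * len(x_tr)))),
        random_state=seed)
    tree.fit(x_tr, y_tr)
    if single_class:
        cv_mean, cv_sd = 1.0, 0.0
        importances = pd.Series(np.zeros(x.shape[1]), index=names)
    else:
        scores = cross_val_score(tree, x_tr, y_tr, cv=5)
        cv_mean, cv_sd = float(scores.mean()), float(scores.std())
        importances = pd.Series(tree.feature_importances_, index=names)
    return TreeMetamodel(tree, names, importances, cv_mean, cv_sd,
                         float(tree.score(x_te, y_te)),
                         [str(c) for c in tree.classes_])


@dataclass
class ResistanceSubspace:
    """One root-to-leaf conjunction of per-parameter intervals ending in a
    leaf predicting the class of interest."""

    constraints: dict[str, tuple[float, float]]  # param -> (lo, hi]; open ends = +-inf
    predicted_class: str
    n_samples: int
    sample_fraction: float
    class_fractions: dict[str, float] = field(default_factory=dict)


def resistance_subspaces(meta: TreeMetamodel,
                         class_of_interest: str = "emerging_metastasis") -> list[ResistanceSubspace]:
    """Compile every leaf predicting ``class_of_interest`` into interval
    constraints (intersecting repeated splits along the path), sorted by leaf
    sample fraction."""
    tree = meta.model.tree_
    classes = meta.classes
    if class_of_interest not in classes:
        return []
    target = classes.index(class_of_interest)
    total = tree.n_node_samples[0]
    out: list[ResistanceSubspace] = []

    def walk(node: int, constraints: dict[str, tuple[float, float]]):
        left, right = tree.children_left[node], tree.children_right[node]
        if left == -1:  # leaf
            counts = tree.value[node][0]
            if int(np.argmax(counts)) == target:
                total_leaf = counts.sum()
                out.append(ResistanceSubspace(
                    {p: iv for p, iv in constraints.items()},
                    class_of_interest,
                    int(tree.n_node_samples[node]),
                    float(tree.n_node_samples[node] / total),
                    {c: float(counts[i] / total_leaf) for i, c in enumerate(classes)}))
            return
        p = meta.feature_names[tree.feature[node]]
        thr = float(tree.threshold[node])
        lo, hi = constraints.get(p, (-np.inf, np.inf))
        walk(left, {**constraints, p: (lo, min(hi, thr))})
        walk(right, {**constraints, p: (max(lo, thr), hi)})

    walk(0, {})
    out.sort(key=lambda s: -s.sample_fraction)
    return out


def local_sensitivity_screen(nominals: dict[str, float],
                             runner: Callable[[dict[str, float], int], tuple],
                             fraction: float = 0.5, n_replicates: int = 3,
                             seed: int = 0) -> pd.Series:
    """One-at-a-time screen: perturb each parameter by +-``fraction`` and
    report the mean absolute change of the outcome value versus nominal.
    A trivial wrapper used only to break ties when the enrichment shortlist
    exceeds the global-analysis budget."""
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(0, 2 ** 31 - 1)) for _ in range(n_replicates)]
    base = np.mean([runner({}, s)[0] for s in seeds])
    effects = {}
    for p, v in nominals.items():
        deltas = []
        for mult in (1.0 - fraction, 1.0 + fraction):
            vals = [runner({p: v * mult}, s)[0] for s in seeds]
            deltas.append(abs(np.mean(vals) - base))
        effects[p] = float(np.mean(deltas))
    return pd.Series(effects).sort_values(ascending=False)
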