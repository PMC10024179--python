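"""Bridge from expression data to model parameters.

Two-group differential expression (responder vs non-responder, Welch t-test
on log2 expression), the rank statistic s_i = sign(logFC_i) * (-log10 p_i),
preranked gene-set enrichment with a gene-sampling permutation null,
Benjamini-Hochberg adjustment, and mapping of significant gene sets to model
parameters via a curated annotation table.

The enrichment score is the classic weighted running-sum statistic: genes are
sorted by decreasing s; hits increment the running sum by |s| / sum(|s| over
hits), misses decrement by 1 / (N - N_hits); ES is the running-sum value of
maximum absolute deviation.  The null distribution per set size comes from
uniformly sampled gene sets; NES divides ES by the mean |null ES| of matching
sign and the p-value is the one-sided permutation tail with add-one smoothing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model_core import ModelParameters

RESPONDER, NON_RESPONDER = "responder", "non_responder"


# ---------------------------------------------------------------------------
# differential expression and ranking

def differential_expression(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-gene log2 fold change (responders minus non-responders) and
    two-sided Welch t-test p-value.

    ``expr`` is genes x samples on log2 scale; ``labels`` maps sample id to
    "responder" / "non_responder".  Each group needs >= 2 samples.
    """
    labels = labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    resp = expr.loc[:, labels == RESPONDER].to_numpy(float)
    nonr = expr.loc[:, labels == NON_RESPONDER].to_numpy(float)
    if resp.shape[1] < 2 or nonr.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples (variance undefined)")
    log_fc = resp.mean(axis=1) - nonr.mean(axis=1)
    t = stats.ttest_ind(resp, nonr, axis=1, equal_var=False)
    return pd.DataFrame({"log_fc": log_fc, "p_value": t.pvalue}, index=expr.index)


def rank_statistic(log_fc, p_value):
    """s = sign(logFC) * (-log10 p); sign(0) = 0; p = 0 is clamped to the
    smallest positive float with a warning."""
    log_fc = np.asarray(log_fc, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to the smallest positive float")
        p = np.where(p == 0, np.nextafter(0.0, 1.0), p)
    s = np.sign(log_fc) * (-np.log10(p))
    return s if s.ndim else float(s)


def rank_genes(de: pd.DataFrame) -> pd.Series:
    """Rank statistic per gene from a differential-expression table."""
    s = rank_statistic(de["log_fc"].to_numpy(), de["p_value"].to_numpy())
    return pd.Series(s, index=de.index, name="s")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# GMT gene-set collections

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# preranked GSEA

def _sorted_stats(ranks: pd.Series):
    """Genes sorted by decreasing rank statistic, ties broken by gene id."""
    s = ranks.sort_index(kind="stable")
    order = np.argsort(-s.to_numpy(), kind="stable")
    genes = s.index.to_numpy()[order]
    return genes, s.to_numpy()[order]


def _es_from_positions(pos_sorted: np.ndarray, w: np.ndarray, n: int):
    """ES (and its running-sum extremum index) for hit positions within the
    sorted gene list with weights w = |s|.  Extrema of the running sum occur
    at hit positions and immediately before them, so only 2m candidates need
    evaluation.  ``pos_sorted``: (..., m) ascending positions."""
    m = pos_sorted.shape[-1]
    wh = w[pos_sorted]
    cw = np.cumsum(wh, axis=-1)
    nr = cw[..., -1:]
    nr = np.where(nr == 0, 1.0, nr)  # all-zero weights: hits contribute 0
    miss = 1.0 / (n - m)
    j = np.arange(1, m + 1)
    at_hit = cw / nr - (pos_sorted + 1 - j) * miss          # value at hit j
    before = (cw - wh) / nr - (pos_sorted - (j - 1)) * miss  # just before hit j
    cand = np.concatenate([at_hit, before], axis=-1)
    idx = np.argmax(np.abs(cand), axis=-1)
    return np.take_along_axis(cand, np.expand_dims(idx, -1), -1)[..., 0], idx


def enrichment_score(ranks: pd.Series, gene_set) -> float:
    """Weighted running-sum enrichment score of one gene set."""
    genes, s = _sorted_stats(ranks)
    w = np.abs(s)
    hits = np.flatnonzero(np.isin(genes, list(gene_set)))
    n = len(genes)
    if hits.size == 0 or hits.size == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the ranked list")
    es, _ = _es_from_positions(hits, w, n)
    return float(es)


def _null_es(w: np.ndarray, n: int, m: int, n_perm: int,
             rng: np.random.Generator, chunk: int = 2000) -> np.ndarray:
    """Null ES distribution for sets of size m: uniformly sampled gene sets."""
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        u = rng.random((k, n))
        pos = np.sort(np.argpartition(u, m, axis=1)[:, :m], axis=1)
        out[done:done + k] = _es_from_positions(pos, w, n)[0]
        done += k
    return out


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    p_adjusted: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    linked_parameters: list[str] = field(default_factory=list)


def preranked_gsea(ranks: pd.Series, sets: dict[str, list[str]],
                   n_permutations: int = 10_000, seed: int = 0,
                   min_size: int = 5, max_size: int = 500) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Returns a DataFrame indexed by set name with columns ``size, es, nes,
    p_value, p_adjusted, leading_edge``.  Sets with fewer than ``min_size``
    (or more than ``max_size``) genes present in the ranked list are skipped
    with a warning.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    genes, s = _sorted_stats(ranks)
    w = np.abs(s)
    n = len(genes)
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in sets.items():
        hits = np.array(sorted(index_of[g] for g in set(members) if g in index_of))
        m = hits.size
        if m == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the ranked list; skipped")
            continue
        if m < min_size or m > max_size:
            continue
        es, ext = _es_from_positions(hits, w, n)
        es = float(es)
        if m not in null_cache:
            null_cache[m] = _null_es(w, n, m, n_permutations, rng)
        null = null_cache[m]
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes, p = np.nan, 1.0
        else:
            nes = es / np.abs(null[same]).mean()
            p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
        # leading edge: hits at or before the extremum (after, for negative ES)
        k = int(ext) % m  # candidate index maps back to hit j (at/before share j)
        if es >= 0:
            le = [genes[i] for i in hits[: k + 1]]
        else:
            le = [genes[i] for i in hits[k:]]
        rows.append((name, m, es, float(nes), float(p), le))
    df = pd.DataFrame(rows, columns=["name", "size", "es", "nes", "p_value",
                                     "leading_edge"]).set_index("name")
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df[["size", "es", "nes", "p_value", "p_adjusted", "leading_edge"]]


# ---------------------------------------------------------------------------
# annotation map and parameter shortlisting

_PARAM_KEYS = {f.name for f in ModelParameters.__dataclass_fields__.values()}


def load_annotation(path) -> dict[str, list[str]]:
    """Load a gene-set -> parameter(s) annotation map (JSON object; values may
    be a parameter name, a list, or ``{"parameters": [...], "rationale": ...}``)."""
    with open(path) as fh:
        raw = json.load(fh)
    return validate_annotation(raw)


def validate_annotation(raw: dict) -> dict[str, list[str]]:
    annotation = {}
    for set_name, v in raw.items():
        if isinstance(v, dict):
            v = v.get("parameters", [])
        if isinstance(v, str):
            v = [v]
        for p in v:
            if p not in _PARAM_KEYS:
                raise ValueError(f"annotation maps {set_name!r} to unknown parameter {p!r}")
        annotation[set_name] = list(v)
    return annotation


def default_annotation() -> dict[str, list[str]]:
    """The shipped curated mapping from enriched gene sets to model
    parameters (10 sets -> 6 parameters)."""
    path = Path(__file__).parent / "data" / "annotation_default.json"
    return load_annotation(path)


@dataclass
class ParameterShortlist:
    """Parameters supported by significantly enriched gene sets, with
    provenance, plus significant-but-unmapped sets (model-expansion
    candidates)."""

    parameters: pd.DataFrame        # index: parameter; columns: best_p_adjusted, sets, directions
    expansion_candidates: list[str]
    alpha: float


def map_sets_to_parameters(results: pd.DataFrame,
                           annotation: dict[str, list[str]],
                           alpha: float = 0.05) -> ParameterShortlist:
    """Link significantly enriched gene sets (BH-adjusted p <= alpha) to model
    parameters through the annotation map."""
    validate_annotation(annotation)
    sig = results[results["p_adjusted"] <= alpha]
    per_param: dict[str, dict] = {}
    expansion = []
    for set_name, row in sig.iterrows():
        params = annotation.get(set_name, [])
        if not params:
            expansion.append(set_name)
            continue
        for p in params:
            entry = per_param.setdefault(p, {"best_p_adjusted": np.inf,
                                             "sets": [], "directions": []})
            entry["best_p_adjusted"] = min(entry["best_p_adjusted"], row["p_adjusted"])
            entry["sets"].append(set_name)
            entry["directions"].append("up" if row["nes"] >= 0 else "down")
    df = pd.DataFrame.from_dict(per_param, orient="index")
    if len(df):
        df = df.sort_values("best_p_adjusted")
    else:
        df = pd.DataFrame(columns=["best_p_adjusted", "sets", "directions"])
    return ParameterShortlist(df, expansion, alpha)
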