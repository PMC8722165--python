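"""ssGSEA scoring, anchor-gene correlation screening, and over-representation tests.

ssGSEA follows the single-sample rank-weighted running-sum formulation: per
sample, genes are ranked by expression (ties get average ranks), the running
sum gains rank^alpha (normalized over the set's hits) at member genes and
loses 1/(N - |S|) at non-members, and the enrichment score is the integral
(sum over positions) of the running-sum deviation. Scores are optionally
normalized by the global (max - min) across the score matrix for
cross-sample comparability.

The correlation screen reproduces the anchor-gene analysis: per-gene Pearson
r against each anchor with two-sided t-based P, significance at |r| > 0.3
and P < 0.001 by default, and the intersection across anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix, GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "SsgseaScores",
    "CorrelationScreen",
    "ssgsea",
    "correlation_screen",
    "overrepresentation",
    "score_group_comparison",
]


@dataclass
class SsgseaScores:
    scores: pd.DataFrame  # sets x samples
    alpha: float
    normalized: bool


def _ssgsea_sample(expr: np.ndarray, ranks: np.ndarray, order: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ES for one (sample, set): walk genes from highest to lowest expression."""
    hits = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    n = len(order)
    n_hit = int(hits.sum())
    hit_inc = np.where(hits, w, 0.0)
    denom = hit_inc.sum()
    p_hit = np.cumsum(hit_inc) / denom
    p_miss = np.cumsum(np.where(hits, 0.0, 1.0)) / (n - n_hit)
    return float(np.sum(p_hit - p_miss))


def ssgsea(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.75,
    normalize: bool = True,
) -> SsgseaScores:
    """Score every (gene set, sample) pair.

    Sets are intersected with the expression universe first; a set with no
    expressed member, or covering the whole universe, is an error.
    """
    genes = np.asarray(X.gene_ids)
    universe = set(genes)
    memberships = {}
    for name in sets.names:
        members = [g for g in sets.genes(name) if g in universe]
        if not members:
            raise ValidationError(f"gene set {name!r} has no gene in the expression matrix")
        if len(members) == len(genes):
            raise ValidationError(f"gene set {name!r} covers the whole gene universe")
        memberships[name] = np.isin(genes, list(members))

    data = X.values.to_numpy(dtype=float)
    out = np.empty((len(memberships), data.shape[1]))
    for j in range(data.shape[1]):
        expr = data[:, j]
        ranks = stats.rankdata(expr, method="average")
        order = np.argsort(-expr, kind="stable")
        for i, in_set in enumerate(memberships.values()):
            out[i, j] = _ssgsea_sample(expr, ranks, order, in_set, alpha)
    if normalize:
        span = out.max() - out.min()
        if span > 0:
            out = out / span
    scores = pd.DataFrame(out, index=list(memberships), columns=X.sample_ids)
    return SsgseaScores(scores=scores, alpha=alpha, normalized=normalize)


@dataclass
class CorrelationScreen:
    r: pd.DataFrame  # genes x anchors
    p: pd.DataFrame
    r_min: float
    p_max: float
    significant: dict[str, list[str]] = field(default_factory=dict)
    intersection: list[str] = field(default_factory=list)


def correlation_screen(
    X: ExpressionMatrix,
    anchors=("PDK1", "PDK2", "PDK3"),
    r_min: float = 0.3,
    p_max: float = 0.001,
) -> CorrelationScreen:
    """Pearson screen of every gene against each anchor gene.

    P values are two-sided from t = r * sqrt((n-2)/(1-r^2)). Each anchor is
    excluded from its own result; the intersection collects genes significant
    for all anchors.
    """
    anchors = list(anchors)
    missing = [a for a in anchors if a not in X.values.index]
    if missing:
        raise ValidationError(f"anchor gene(s) absent from matrix: {missing}")
    n = len(X.sample_ids)
    if n < 4:
        raise ValidationError("correlation screen needs >= 4 samples")

    data = X.values.to_numpy(dtype=float)
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    genes = np.asarray(X.gene_ids)
    r_cols, p_cols = {}, {}
    for a in anchors:
        av = centered[X.values.index.get_loc(a)]
        an = np.linalg.norm(av)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (centered @ av) / (norms * an)
        r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        r_cols[a], p_cols[a] = r, p

    r_df = pd.DataFrame(r_cols, index=genes)
    p_df = pd.DataFrame(p_cols, index=genes)
    significant = {}
    for a in anchors:
        mask = (r_df[a].abs() > r_min) & (p_df[a] < p_max)
        mask[a] = False  # anchor never reported against itself
        significant[a] = [str(g) for g in genes[mask.to_numpy()]]
    inter = set(significant[anchors[0]])
    for a in anchors[1:]:
        inter &= set(significant[a])
    return CorrelationScreen(
        r=r_df,
        p=p_df,
        r_min=r_min,
        p_max=p_max,
        significant=significant,
        intersection=sorted(inter),
    )


def overrepresentation(
    query_genes, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list.

    Per set: P = P(overlap >= observed) under sampling |query| genes from the
    universe; BH-adjusted q across all tested sets. Sets are intersected with
    the universe before testing. Requires query subset of universe.
    """
    universe = list(dict.fromkeys(universe))
    query = list(dict.fromkeys(query_genes))
    if not query or not universe:
        raise ValidationError("query and universe must be non-empty")
    uset = set(universe)
    outside = [g for g in query if g not in uset]
    if outside:
        raise ValidationError(f"query gene(s) outside the universe: {outside[:5]}")
    M, n_query = len(universe), len(query)
    qset = set(query)
    rows = []
    for name in collection.names:
        members = [g for g in collection.genes(name) if g in uset]
        if not members:
            continue
        k = len(qset & set(members))
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n_query))
        rows.append((name, k, len(members), n_query, M, min(max(p, np.nextafter(0, 1)), 1.0)))
    if not rows:
        raise ValidationError("no gene set overlaps the universe")
    df = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"]
    ).set_index("set")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def score_group_comparison(scores, labels) -> pd.DataFrame:
    """One-way ANOVA of each score row across subtype groups.

    ``scores`` is a DataFrame (scores x samples) or Series; groups with < 2
    samples are dropped with a warning; < 2 usable groups is an error.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(scores.name or "score").T
    labels = pd.Series(labels, index=scores.columns) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(scores.columns)
    counts = labels.value_counts()
    keep_groups = counts[counts >= 2].index
    dropped = counts[counts < 2].index.tolist()
    if dropped:
        log.warning("dropping group(s) with < 2 samples: %s", dropped)
    if len(keep_groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups with >= 2 samples each")
    rows = []
    for name, row in scores.iterrows():
        groups = [row[labels == g].to_numpy(dtype=float) for g in keep_groups]
        with np.errstate(invalid="ignore", divide="ignore"):
            F, p = stats.f_oneway(*groups)
        rows.append((name, float(F), float(p)))
    return pd.DataFrame(rows, columns=["score", "F", "p"]).set_index("score")
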