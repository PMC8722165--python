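"""Resampling consensus clustering of pathway genes with CDF/delta-area model selection.

Items are genes (rows of a Z-scored expression matrix), features are samples.
Per resampling rep a fraction ``p_item`` of items (and ``p_feature`` of
features) is drawn without replacement and clustered by average-linkage
agglomerative hierarchical clustering on euclidean distances; the consensus
matrix entry M_k[i, j] is the number of times i and j co-clustered divided by
the number of times both were sampled together (the unbiased denominator
under item subsampling). The cluster count k is chosen from the empirical CDF
of consensus values: A(k) is the area under the CDF and the relative
delta-area criterion picks the largest k whose relative gain exceeds a
threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["ConsensusResult", "zscore_rows", "consensus_cluster", "select_pathway_modules"]


def zscore_rows(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sd 1 (ddof=1).

    Zero-sd genes are dropped with a warning listing them.
    """
    vals = X.values.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(X.gene_ids, keep) if not k]
    if dropped:
        log.warning("dropping %d constant gene(s) before Z-scoring: %s", len(dropped), dropped[:10])
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return ExpressionMatrix(
        pd.DataFrame(z, index=np.asarray(X.gene_ids)[keep], columns=X.values.columns),
        X.cohort.copy(),
    )


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, CDF areas, delta-areas and final labels."""

    items: list[str]
    k_values: list[int]
    consensus: dict[int, np.ndarray]  # items x items, symmetric, diag 1
    labels: dict[int, np.ndarray]  # 1-based cluster labels per item
    area: dict[int, float]  # A(k)
    delta_area: dict[int, float]  # relative change; A(k) itself at the first k
    chosen_k: int
    fixed_k: int | None = None
    reps: int = 0
    p_item: float = 1.0
    p_feature: float = 1.0
    seed: int | None = None
    co_sampled: np.ndarray = field(default=None, repr=False)

    def cluster_members(self, k: int | None = None) -> dict[int, list[str]]:
        k = self.chosen_k if k is None else k
        lab = self.labels[k]
        return {
            c: [self.items[i] for i in np.flatnonzero(lab == c)] for c in np.unique(lab)
        }

    def intra_cluster_consensus(self, k: int | None = None) -> dict[int, float]:
        """Mean off-diagonal consensus within each cluster (singletons -> 1.0)."""
        k = self.chosen_k if k is None else k
        M, lab = self.consensus[k], self.labels[k]
        out = {}
        for c in np.unique(lab):
            idx = np.flatnonzero(lab == c)
            if len(idx) < 2:
                out[int(c)] = 1.0
            else:
                sub = M[np.ix_(idx, idx)]
                out[int(c)] = float(sub[np.triu_indices(len(idx), k=1)].mean())
        return out


def _ecdf_area(values: np.ndarray) -> float:
    """Exact area under the empirical step CDF of consensus values over [0, 1]."""
    x = np.sort(values)
    F = np.arange(1, len(x) + 1) / len(x)
    xs = np.concatenate([x, [1.0]])
    return float(np.sum(F * np.diff(xs)))


def consensus_cluster(
    Z: ExpressionMatrix,
    k_range=range(2, 11),
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int | None = None,
    fixed_k: int | None = None,
    delta_threshold: float = 0.05,
) -> ConsensusResult:
    """Consensus-cluster the genes of ``Z`` over ``k_range``.

    Defaults follow the reference resampling scheme: 1000 reps, 80% item
    subsampling, all features, hierarchical clustering (average linkage,
    euclidean). ``fixed_k`` overrides the delta-area criterion.
    """
    items = Z.gene_ids
    data = Z.values.to_numpy(dtype=float)
    n, m = data.shape
    k_values = sorted(set(int(k) for k in k_range) | ({int(fixed_k)} if fixed_k else set()))
    if min(k_values) < 2 or max(k_values) > n - 1:
        raise ValidationError(f"k_range must lie within [2, {n - 1}] for {n} items")
    n_sub = math.ceil(p_item * n)
    m_sub = math.ceil(p_feature * m)
    if n_sub < max(k_values) + 1:
        raise ValidationError("p_item leaves fewer items than max(k)+1 per rep")

    rng = np.random.default_rng(seed)
    co_cluster = {k: np.zeros((n, n)) for k in k_values}
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        if m_sub < m:
            feats = np.sort(rng.choice(m, size=m_sub, replace=False))
            sub = data[np.ix_(idx, feats)]
        else:
            sub = data[idx]
        link = linkage(sub, method="average", metric="euclidean")
        co_sample[np.ix_(idx, idx)] += 1
        for k in k_values:
            lab = fcluster(link, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    off = ~np.eye(n, dtype=bool)
    if (co_sample[off] == 0).any():
        raise ValidationError(
            "some item pairs were never co-sampled; increase reps (or p_item)"
        )
    consensus, labels, area = {}, {}, {}
    iu = np.triu_indices(n, k=1)
    for k in k_values:
        with np.errstate(invalid="ignore"):
            M = np.where(co_sample > 0, co_cluster[k] / np.where(co_sample > 0, co_sample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        final = linkage(squareform(1.0 - M, checks=False), method="average")
        labels[k] = fcluster(final, t=k, criterion="maxclust")
        area[k] = _ecdf_area(M[iu])

    delta = {}
    prev = None
    for k in k_values:
        delta[k] = area[k] if prev is None else (area[k] - area[prev]) / area[prev]
        prev = k
    if fixed_k is not None:
        chosen = int(fixed_k)
    else:
        passing = [k for k in k_values if delta[k] > delta_threshold]
        chosen = max(passing) if passing else k_values[0]

    return ConsensusResult(
        items=list(items),
        k_values=k_values,
        consensus=consensus,
        labels=labels,
        area=area,
        delta_area=delta,
        chosen_k=chosen,
        fixed_k=fixed_k,
        reps=reps,
        p_item=p_item,
        p_feature=p_feature,
        seed=seed,
        co_sampled=co_sample,
    )


def _mean_pairwise_correlation(Z: ExpressionMatrix, genes: list[str]) -> float:
    sub = Z.values.loc[genes].to_numpy(dtype=float)
    r = np.corrcoef(sub)
    return float(r[np.triu_indices(len(genes), k=1)].mean())


def select_pathway_modules(
    result: ConsensusResult,
    glycolysis_set,
    cholesterol_set,
    Z: ExpressionMatrix | None = None,
    k: int | None = None,
    min_size: int = 3,
    consensus_tol: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Pick the robust co-expressed module for each pathway.

    Each cluster is labeled by the pathway of the majority of its members;
    for each pathway the cluster with the highest mean intra-cluster
    consensus among that pathway's clusters with >= ``min_size`` members is
    returned. Clusters whose consensus lies within ``consensus_tol`` of the
    pathway's best are treated as equally robust (consensus saturates once
    every block co-clusters in nearly every rep, so small gaps are
    resampling noise); such ties break by mean within-cluster pairwise
    correlation on ``Z`` — the most strongly co-expressed cluster wins —
    falling back to cluster size when no expression matrix is supplied. Every clustered item
    must belong to exactly one pathway set.
    """
    gly = set(glycolysis_set)
    cho = set(cholesterol_set)
    both = gly & cho
    if both:
        raise ValidationError(f"genes in both pathway sets: {sorted(both)[:5]}")
    unknown = [i for i in result.items if i not in gly | cho]
    if unknown:
        raise ValidationError(f"clustered items in neither pathway set: {unknown[:5]}")

    members = result.cluster_members(k)
    cons = result.intra_cluster_consensus(k)
    by_pathway: dict[str, list[tuple[float, int, list[str]]]] = {}
    for c, genes in members.items():
        if len(genes) < min_size:
            continue
        n_gly = sum(g in gly for g in genes)
        pathway = "glycolysis" if n_gly * 2 > len(genes) else "cholesterol"
        if n_gly * 2 == len(genes):  # exact tie: assign by first member
            pathway = "glycolysis" if genes[0] in gly else "cholesterol"
        by_pathway.setdefault(pathway, []).append((cons[c], len(genes), genes))

    chosen: dict[str, list[str]] = {}
    for pathway in ("glycolysis", "cholesterol"):
        candidates = by_pathway.get(pathway)
        if not candidates:
            raise ValidationError(
                f"no cluster with >= {min_size} members has a {pathway} majority"
            )
        top = max(c[0] for c in candidates)
        tied = [c for c in candidates if c[0] >= top - consensus_tol]
        if len(tied) > 1 and Z is not None:
            tied.sort(key=lambda c: _mean_pairwise_correlation(Z, c[2]), reverse=True)
        else:
            tied.sort(key=lambda c: (c[0], c[1]), reverse=True)
        chosen[pathway] = list(tied[0][2])
    return chosen["glycolysis"], chosen["cholesterol"]
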