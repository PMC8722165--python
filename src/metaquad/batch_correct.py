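"""Parametric empirical-Bayes batch correction (ComBat) and a PCA-based check.

The model: for gene g, sample j in batch b,

    x_gbj = alpha_g + gamma_bg + delta_bg * eps,   eps ~ N(0, sigma_g^2)

Each gene is standardized by its grand mean and pooled residual sd, per-batch
location (gamma) and scale (delta^2) are estimated, shrunk with conjugate
priors — normal on locations, inverse-gamma on scales, hyper-parameters by
method of moments — via the usual iterative joint update, and the data are
adjusted and back-transformed. No covariate design and mean+scale adjustment,
i.e. the published defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ConvergenceError, ValidationError
from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["BatchModel", "combat_correct", "pca_batch_check"]


@dataclass
class BatchModel:
    """Fitted EB batch-adjustment parameters (batches x genes arrays)."""

    batches: list[str]
    genes: list[str]
    grand_mean: np.ndarray  # per gene
    var_pooled: np.ndarray  # per gene
    gamma_hat: np.ndarray  # raw standardized batch locations
    delta_hat: np.ndarray  # raw standardized batch variances
    gamma_star: np.ndarray  # EB-shrunken locations
    delta_star: np.ndarray  # EB-shrunken variances
    gamma_bar: np.ndarray  # per-batch prior means
    t2: np.ndarray  # per-batch prior variances
    a_prior: np.ndarray
    b_prior: np.ndarray
    n_iter: np.ndarray
    skipped_genes: list[str]

    def __post_init__(self) -> None:
        if (self.delta_star <= 0).any():
            raise ValidationError("shrunken batch variances must be positive")


def _postmean(g_hat, g_bar, n, d_old, t2):
    return (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_solve(s_data, g_hat, d_hat, g_bar, t2, a, b, tol=1e-6, max_iter=500):
    """Iterative joint update of the EB posterior location/scale for one batch."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.abs(g_old).clip(1e-12)),
            np.max(np.abs(d_new - d_old) / np.abs(d_old).clip(1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            return g_new, d_new, it
    raise ConvergenceError(f"EB update did not converge within {max_iter} iterations")


def combat_correct(X: ExpressionMatrix, tol: float = 1e-6) -> tuple[ExpressionMatrix, BatchModel]:
    """Remove cohort batch effects; returns (corrected matrix, fitted model).

    Requires >=2 batches with >=2 samples each. Genes with zero pooled
    residual variance are passed through uncorrected with a warning.
    """
    cohort = X.cohort
    batches = list(dict.fromkeys(cohort))
    if len(batches) < 2:
        raise ValidationError("batch correction needs >= 2 batches")
    counts = cohort.value_counts()
    tiny = counts[counts < 2]
    if len(tiny):
        raise ValidationError(
            f"batch(es) with a single sample: {list(tiny.index)}; "
            "exclude them (or merge) before correction"
        )

    data = X.values.to_numpy(dtype=float)
    masks = [cohort.to_numpy() == b for b in batches]
    n_b = np.array([m.sum() for m in masks])
    n_total = data.shape[1]

    # per-batch means and pooled residual variance
    batch_means = np.stack([data[:, m].mean(axis=1) for m in masks])  # B x G
    grand_mean = (n_b / n_total) @ batch_means
    fitted = np.zeros_like(data)
    for bm, m in zip(batch_means, masks):
        fitted[:, m] = bm[:, None]
    var_pooled = ((data - fitted) ** 2).mean(axis=1)

    ok = var_pooled > 0
    skipped = [g for g, keep in zip(X.gene_ids, ok) if not keep]
    if skipped:
        log.warning(
            "%d zero-variance gene(s) passed through uncorrected: %s",
            len(skipped),
            skipped[:5],
        )
    sd = np.sqrt(var_pooled[ok])
    s_data = (data[ok] - grand_mean[ok][:, None]) / sd[:, None]

    G = int(ok.sum())
    B = len(batches)
    gamma_hat = np.stack([s_data[:, m].mean(axis=1) for m in masks])
    delta_hat = np.stack([s_data[:, m].var(axis=1, ddof=1) for m in masks])

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m_d = delta_hat.mean(axis=1)
    s2_d = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2_d + m_d**2) / s2_d
    b_prior = (m_d * s2_d + m_d**3) / s2_d

    gamma_star = np.empty((B, G))
    delta_star = np.empty((B, G))
    n_iter = np.empty(B, dtype=int)
    adjusted = s_data.copy()
    for b, m in enumerate(masks):
        g_star, d_star, it = _it_solve(
            s_data[:, m], gamma_hat[b], delta_hat[b], gamma_bar[b], t2[b], a_prior[b], b_prior[b],
            tol=tol,
        )
        gamma_star[b], delta_star[b], n_iter[b] = g_star, d_star, it
        adjusted[:, m] = (s_data[:, m] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = data.copy()
    out[ok] = adjusted * sd[:, None] + grand_mean[ok][:, None]

    model = BatchModel(
        batches=[str(b) for b in batches],
        genes=[g for g, keep in zip(X.gene_ids, ok) if keep],
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        t2=t2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=n_iter,
        skipped_genes=skipped,
    )
    corrected = ExpressionMatrix(
        pd.DataFrame(out, index=X.values.index, columns=X.values.columns), cohort.copy()
    )
    return corrected, model


def pca_batch_check(X_before: ExpressionMatrix, X_after: ExpressionMatrix) -> dict:
    """Quantify batch structure in PC1-2 space before vs after correction.

    Computes top-2 PC scores on gene-centered data and the mean silhouette of
    the batch labels in that plane. A well-corrected matrix drops the
    silhouette to ~0 or below.
    """
    if X_before.sample_ids != X_after.sample_ids:
        raise ValidationError("before/after matrices must share samples (same order)")
    if len(X_before.sample_ids) < 3:
        raise ValidationError("PCA batch check needs >= 3 samples")
    labels = X_before.cohort.to_numpy()
    report = {}
    for tag, X in (("before", X_before), ("after", X_after)):
        centered = X.values.to_numpy() - X.values.to_numpy().mean(axis=1, keepdims=True)
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(centered.T)
        report[f"variance_explained_{tag}"] = pca.explained_variance_ratio_.tolist()
        report[f"silhouette_{tag}"] = float(silhouette_score(coords, labels))
        report[f"pc_scores_{tag}"] = pd.DataFrame(
            coords, index=X.sample_ids, columns=["PC1", "PC2"]
        )
    return report
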