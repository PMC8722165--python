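"""Reference-based immune-cell deconvolution by nu-support-vector regression.

Per bulk sample the mixture is regressed on the signature matrix with a
linear-kernel nu-SVR over a small nu grid; the best nu by reconstruction
RMSE wins, negative coefficients are clipped to zero and the rest normalized
to fractions summing to 1. Significance is a permutation P: the fraction of
random gene-label permutations of the sample whose reconstruction
correlation reaches the observed one. Mixture and signature are each
standardized globally (whole-matrix mean/sd), which also makes the estimate
invariant to a global positive scaling of the mixture. Quantile
normalization of microarray inputs is deliberately omitted: inputs are
assumed comparably normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = ["SignatureMatrix", "FractionEstimate", "deconvolve", "fraction_group_comparison"]

NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class SignatureMatrix:
    """Marker genes x cell types reference profile."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 2:
            raise ValidationError("signature needs >= 2 cell types")
        if v.index.duplicated().any():
            raise ValidationError("duplicate marker genes in signature")
        if (v.to_numpy() == 0).all(axis=0).any():
            raise ValidationError("signature contains an all-zero cell-type column")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class FractionEstimate:
    """Per-sample cell-type fractions with fit quality and permutation P."""

    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    rmse: pd.Series
    correlation: pd.Series
    p_perm: pd.Series
    nu: pd.Series
    degenerate: list[str]  # samples where all coefficients were <= 0

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if (f < 0).any():
            raise ValidationError("fractions must be non-negative")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("fractions must sum to 1 per sample")


def _zscore_global(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def _fit_sample(Xz: np.ndarray, yz: np.ndarray, nu_grid=NU_GRID):
    """Fit the nu grid, return (weights, rmse, corr, nu) of the best fit."""
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-6)
        model.fit(Xz, yz)
        w = model.coef_.ravel()
        recon = Xz @ w + model.intercept_
        rmse = float(np.sqrt(np.mean((recon - yz) ** 2)))
        if best is None or rmse < best[1]:
            corr = float(np.corrcoef(recon, yz)[0, 1])
            best = (w, rmse, corr, nu)
    return best


def deconvolve(
    mixtures,
    signature,
    n_perm: int = 1000,
    seed: int | None = None,
    nu_grid=NU_GRID,
) -> FractionEstimate:
    """Estimate cell-type fractions for every sample of ``mixtures``.

    ``mixtures`` is an ExpressionMatrix or genes x samples DataFrame;
    ``signature`` a SignatureMatrix or DataFrame. Needs >= 10 shared genes.
    With ``n_perm`` = 0 permutation P values are NaN. A sample whose SVR
    coefficients are all <= 0 receives uniform fractions and is flagged.
    """
    mix = mixtures.values if isinstance(mixtures, ExpressionMatrix) else mixtures
    sig = signature.values if isinstance(signature, SignatureMatrix) else signature
    SignatureMatrix(sig)  # validate
    shared = [g for g in sig.index if g in set(mix.index)]
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared genes between mixture and signature (need >= 10)")
    S = sig.loc[shared].to_numpy(dtype=float)
    M = mix.loc[shared].to_numpy(dtype=float)
    Xz = _zscore_global(S)
    rng = np.random.default_rng(seed)

    k = S.shape[1]
    rows, rmses, corrs, ps, nus, degenerate = [], [], [], [], [], []
    for j, sample in enumerate(mix.columns):
        yz = _zscore_global(M[:, j])
        w, rmse, corr, nu = _fit_sample(Xz, yz, nu_grid)
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            log.warning("sample %s: all SVR coefficients <= 0; returning uniform fractions", sample)
            f = np.full(k, 1.0 / k)
            degenerate.append(str(sample))
        else:
            f = w / w.sum()
        if n_perm > 0:
            null = np.empty(n_perm)
            for b in range(n_perm):
                yp = rng.permutation(yz)
                model = NuSVR(kernel="linear", nu=nu, C=1.0, tol=1e-6)
                model.fit(Xz, yp)
                recon = Xz @ model.coef_.ravel() + model.intercept_
                null[b] = np.corrcoef(recon, yp)[0, 1]
            p = float(np.mean(null >= corr))
        else:
            p = float("nan")
        rows.append(f)
        rmses.append(rmse)
        corrs.append(corr)
        ps.append(p)
        nus.append(nu)

    idx = pd.Index(mix.columns, name="sample")
    return FractionEstimate(
        fractions=pd.DataFrame(rows, index=idx, columns=sig.columns),
        rmse=pd.Series(rmses, index=idx, name="rmse"),
        correlation=pd.Series(corrs, index=idx, name="correlation"),
        p_perm=pd.Series(ps, index=idx, name="p_perm"),
        nu=pd.Series(nus, index=idx, name="nu"),
        degenerate=degenerate,
    )


def fraction_group_comparison(F: FractionEstimate | pd.DataFrame, labels) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis of each cell type's fractions across groups.

    Returns per cell type H, chi-square P and BH q. A cell type tied across
    all samples gets H = 0, P = 1 with a warning.
    """
    frac = F.fractions if isinstance(F, FractionEstimate) else F
    labels = pd.Series(labels).reindex(frac.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a group label")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValidationError("group comparison needs >= 2 groups")
    rows = []
    for ct in frac.columns:
        vals = [frac.loc[labels == g, ct].to_numpy(dtype=float) for g in groups]
        flat = np.concatenate(vals)
        if np.all(flat == flat[0]):
            log.warning("cell type %s: all values tied; P set to 1", ct)
            rows.append((ct, 0.0, 1.0))
            continue
        H, p = stats.kruskal(*vals)
        rows.append((ct, float(H), float(p)))
    out = pd.DataFrame(rows, columns=["cell_type", "H", "p"]).set_index("cell_type")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
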