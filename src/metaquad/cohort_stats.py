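"""Survival analysis and categorical comparisons across metabolic subtypes.

Kaplan-Meier curves, k-group log-rank tests and Cox proportional-hazards
fits (Efron tie handling) are delegated to lifelines behind this module's
surface. Contingency machinery is authored here: Fisher's exact test for
r x c tables by full margin-conditioned enumeration (Freeman-Halton, used
when the table total is small) with a Monte Carlo fallback at larger totals,
chi-square association with an automatic switch to the exact test when any
expected count falls below 5, and Benjamini-Hochberg adjustment across
gene families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ConvergenceError, ValidationError
from .io_formats import ClinicalTable, VariantTable

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalFit",
    "CoxResult",
    "ContingencyResult",
    "km_logrank",
    "cox_fit",
    "fisher_exact_rxc",
    "alteration_frequency_test",
    "categorical_association",
]


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalFit:
    """Per-group KM step functions and the k-group log-rank test."""

    km: dict[str, pd.DataFrame]  # per group: time, survival, at_risk
    logrank_stat: float
    logrank_p: float
    dof: int


@dataclass
class CoxResult:
    """Cox PH fit: coefficients are log hazard ratios vs the references."""

    summary: pd.DataFrame  # coef, se, z, p, ci_lower, ci_upper, hr
    n: int
    n_events: int
    n_dropped: int
    log_likelihood: float


def _clinical_frame(clinical) -> pd.DataFrame:
    if isinstance(clinical, ClinicalTable):
        return clinical.records
    return clinical


def km_logrank(clinical, groups) -> SurvivalFit:
    """Kaplan-Meier per group plus the k-group log-rank chi-square test.

    ``groups`` is a per-sample label Series aligned to the clinical table.
    Requires >= 2 groups and at least one event overall; an all-censored
    group is allowed (it still contributes expected counts).
    """
    df = _clinical_frame(clinical)
    groups = pd.Series(groups).reindex(df.index)
    if groups.isna().any():
        raise ValidationError("every sample needs a group label")
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    if int(df["event"].sum()) == 0:
        raise ValidationError("log-rank needs at least one event")

    km = {}
    for g in levels:
        sub = df[groups == g]
        fitter = KaplanMeierFitter()
        fitter.fit(sub["time"], sub["event"], label=str(g))
        table = fitter.event_table
        km[str(g)] = pd.DataFrame(
            {
                "time": fitter.survival_function_.index.to_numpy(),
                "survival": fitter.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": table["at_risk"].reindex(fitter.survival_function_.index).to_numpy(),
            }
        )
    res = multivariate_logrank_test(df["time"], groups, df["event"])
    return SurvivalFit(
        km=km,
        logrank_stat=float(res.test_statistic),
        logrank_p=float(res.p_value),
        dof=len(levels) - 1,
    )


def cox_fit(
    clinical,
    labels=None,
    covariates=("age", "gender", "grade", "stage", "molecular_phenotype"),
    subtype_reference: str = "quiescent",
) -> CoxResult:
    """Multivariable Cox PH fit with Efron tie handling.

    The subtype label (if given) is dummy-coded against ``subtype_reference``;
    other categorical covariates against their first sorted level. Rows with
    a missing covariate are list-wise deleted (logged). Diverging
    coefficients (|beta| > 20) raise, advising exact/penalized handling.
    """
    df = _clinical_frame(clinical)
    design = df[["time", "event"]].copy()
    if labels is not None:
        lab = pd.Series(labels).reindex(df.index)
        others = [l for l in pd.unique(lab.dropna()) if l != subtype_reference]
        for level in sorted(map(str, others)):
            design[f"subtype_{level}"] = (lab.astype(str) == level).astype(float)
        design.loc[lab.isna(), f"subtype_{sorted(map(str, others))[0]}"] = np.nan
    for cov in covariates:
        if cov not in df.columns:
            raise ValidationError(f"covariate {cov!r} absent from clinical table")
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = pd.to_numeric(col)
        else:
            col = col.astype(object)
            levels = sorted(map(str, pd.unique(col.dropna())))
            if len(levels) < 2:
                raise ValidationError(f"covariate {cov!r} is constant")
            for level in levels[1:]:
                design[f"{cov}_{level}"] = (col.astype(str) == level).astype(float)
            design.loc[col.isna(), f"{cov}_{levels[1]}"] = np.nan

    before = len(design)
    design = design.dropna()
    n_dropped = before - len(design)
    if n_dropped:
        log.info("Cox fit: list-wise deleted %d sample(s) with missing covariates", n_dropped)
    const = [c for c in design.columns[2:] if design[c].nunique() <= 1]
    if const:
        raise ValidationError(f"constant covariate column(s) after deletion: {const}")
    n_events = int(design["event"].sum())
    if n_events < design.shape[1] - 2:
        raise ValidationError("fewer events than coefficients")

    cph = CoxPHFitter()  # lifelines defaults: Efron ties, Newton-Raphson
    try:
        import warnings

        from lifelines.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # a still-large Newton step at termination signals separation
            warnings.simplefilter("error", ConvergenceWarning)
            cph.fit(design, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/Warning variants
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    if (cph.params_.abs() > 20).any():
        raise ConvergenceError(
            "diverging coefficient (|beta| > 20): likely complete separation; "
            "consider Firth or exact conditional handling (not implemented)"
        )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
            "ci_lower": s["coef lower 95%"],
            "ci_upper": s["coef upper 95%"],
            "hr": np.exp(s["coef"]),
        }
    )
    return CoxResult(
        summary=summary,
        n=len(design),
        n_events=n_events,
        n_dropped=n_dropped,
        log_likelihood=float(cph.log_likelihood_),
    )


# ---------------------------------------------------------------------------
# exact contingency tests


def _log_table_prob(tables: np.ndarray, row_margins: np.ndarray, col_margins: np.ndarray) -> np.ndarray:
    """log P of tables under the margin-conditioned (multiv. hypergeom.) null.

    ``tables`` has shape (..., r, c); P = prod(R_i!) prod(C_j!) / (N! prod n_ij!).
    """
    N = row_margins.sum()
    const = gammaln(row_margins + 1).sum() + gammaln(col_margins + 1).sum() - gammaln(N + 1)
    return const - gammaln(tables + 1.0).sum(axis=(-2, -1))


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray) -> np.ndarray:
    """All non-negative integer r x c tables with the given margins."""
    r, c = len(row_margins), len(col_margins)
    out = []
    table = np.zeros((r, c), dtype=np.int64)

    def fill_row(i: int, remaining_cols: np.ndarray) -> None:
        if i == r - 1:
            if (remaining_cols >= 0).all():
                table[i] = remaining_cols
                out.append(table.copy())
            return
        target = row_margins[i]

        def fill_cell(j: int, left: int) -> None:
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    table[i, j] = left
                    fill_row(i + 1, remaining_cols - table[i])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                table[i, j] = v
                fill_cell(j + 1, left - v)

        fill_cell(0, target)

    fill_row(0, col_margins.astype(np.int64))
    return np.array(out) if out else np.zeros((0, r, c), dtype=np.int64)


def fisher_exact_rxc(
    table,
    max_exact_total: int = 200,
    n_mc: int = 100_000,
    mc_seed: int = 12345,
) -> tuple[float, str]:
    """Two-sided Fisher exact test for an r x c table.

    Exact (Freeman-Halton) by full enumeration of margin-compatible tables
    when the total is <= ``max_exact_total``; otherwise Monte Carlo with
    ``n_mc`` draws from the margin-conditioned null at a fixed seed. The
    two-sided P sums the probabilities of tables no more probable than the
    observed one. Returns (P, method).
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("table must be a 2-D array of non-negative integers")
    R = obs.sum(axis=1)
    C = obs.sum(axis=0)
    N = int(obs.sum())
    if N == 0:
        raise ValidationError("empty table")
    log_p_obs = float(_log_table_prob(obs[None], R, C)[0])
    tol = 1e-7  # relative slack against float round-off, as in the R reference

    if N <= max_exact_total:
        all_tables = _enumerate_tables(R, C)
        lp = _log_table_prob(all_tables, R, C)
        p = float(np.exp(lp[lp <= log_p_obs + tol]).sum())
        return min(p, 1.0), "exact"

    rng = np.random.default_rng(mc_seed)
    if obs.shape[1] == 2:
        # r x 2: draw the 'altered' column directly from the multiv. hypergeometric
        a = rng.multivariate_hypergeometric(R, int(C[0]), size=n_mc)
        draws = np.stack([a, R[None, :] - a], axis=-1)
    else:
        # general: permute column assignments of N row-labelled units
        units = np.repeat(np.arange(len(R)), R)
        splits = np.cumsum(C)[:-1]
        draws = np.empty((n_mc, len(R), len(C)), dtype=np.int64)
        for b in range(n_mc):
            rng.shuffle(units)
            for j, part in enumerate(np.split(units, splits)):
                draws[b, :, j] = np.bincount(part, minlength=len(R))
    lp = _log_table_prob(draws, R, C)
    p = float((np.count_nonzero(lp <= log_p_obs + tol) + 1) / (n_mc + 1))
    return min(p, 1.0), "monte_carlo"


@dataclass
class ContingencyResult:
    table: pd.DataFrame
    test: str  # chi-square | fisher_exact | fisher_monte_carlo
    statistic: float | None
    p: float
    q: float | None = None
    frequencies: pd.Series | None = field(default=None, repr=False)


def alteration_frequency_test(
    variants: VariantTable,
    labels,
    genes,
    mode: str = "any_alteration",
    max_exact_total: int = 200,
    n_mc: int = 100_000,
    mc_seed: int = 12345,
) -> dict[str, ContingencyResult]:
    """Per-gene subtype x altered/not Fisher tests with BH adjustment.

    ``mode`` is one of any_alteration, cnv_loss, cnv_gain, snv. Genes absent
    from the variant table are skipped with a warning. Per-subtype alteration
    frequencies are reported in percent.
    """
    labels = pd.Series(labels)
    missing = [s for s in variants.samples if s not in labels.index]
    if missing:
        raise ValidationError(f"labels missing for sample(s): {missing[:5]}")
    labels = labels.reindex(variants.samples)
    levels = [l for l in ("quiescent", "glycolytic", "cholesterogenic", "mixed") if l in set(labels)]
    levels += [l for l in pd.unique(labels) if l not in levels]

    known = set(variants.cnv.index) | {g for g, _, _ in variants.snv_indel}
    results: dict[str, ContingencyResult] = {}
    for gene in genes:
        if gene not in known:
            log.warning("gene %s absent from variant table; skipped", gene)
            continue
        altered = variants.altered(gene, mode)
        tab = pd.DataFrame(
            {
                "altered": [int(altered[labels == l].sum()) for l in levels],
                "not_altered": [int((~altered[labels == l]).sum()) for l in levels],
            },
            index=pd.Index(levels, name="subtype"),
        )
        p, method = fisher_exact_rxc(
            tab.to_numpy(), max_exact_total=max_exact_total, n_mc=n_mc, mc_seed=mc_seed
        )
        freq = (100.0 * tab["altered"] / tab.sum(axis=1)).round(1)
        freq.name = "percent_altered"
        results[gene] = ContingencyResult(
            table=tab, test=f"fisher_{method}", statistic=None, p=p, frequencies=freq
        )
    if not results:
        raise ValidationError("no requested gene present in the variant table")
    qs = multipletests([r.p for r in results.values()], method="fdr_bh")[1]
    for res, q in zip(results.values(), qs):
        res.q = float(q)
    return results


def categorical_association(labels, column) -> ContingencyResult:
    """Association between subtype labels and a categorical clinical column.

    Chi-square without continuity correction on the r x c crosstab; switches
    to the Fisher exact machinery (logged) when any expected count is < 5.
    """
    labels = pd.Series(labels)
    column = pd.Series(column).reindex(labels.index)
    keep = labels.notna() & column.notna()
    labels, column = labels[keep], column[keep]
    if labels.nunique() < 2 or column.nunique() < 2:
        raise ValidationError("both variables need >= 2 observed levels")
    tab = pd.crosstab(labels, column)
    chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    if (expected < 5).any():
        log.info("expected count < 5; using Fisher exact instead of chi-square")
        p, method = fisher_exact_rxc(tab.to_numpy())
        return ContingencyResult(table=tab, test=f"fisher_{method}", statistic=None, p=float(p))
    return ContingencyResult(table=tab, test="chi-square", statistic=float(chi2), p=float(p))
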