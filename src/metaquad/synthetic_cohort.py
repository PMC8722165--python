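"""Synthetic multi-cohort generator with the structure the pipeline assumes.

The generator emulates a merged tumor expression study: three cohorts of
log2-scale expression with cohort-level batch effects, two planted
co-expressed metabolic modules (12 glycolytic + 8 cholesterogenic genes)
driven by latent quadrant activities, decoy pathway genes, immune-mixture
marker genes, proportional-hazards survival linked to subtype, clinical
covariates, and subtype-dependent copy-number loss rates for two
tumor-suppressor-like genes (named RB1 and LRP1B after the genes whose loss
pattern they emulate).

Each sample's latent activity pair (a_g, a_c) is drawn from a 2-D Gaussian
whose mean sits inside the quadrant matching the sample's subtype label and
which is truncated (by rejection) to that quadrant's signs, so the
median-sign quadrant rule is the Bayes rule by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import ClinicalTable, ExpressionMatrix, GeneSetCollection, VariantTable

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohorts", "simulate_mixture"]

SUBTYPES = ("quiescent", "glycolytic", "cholesterogenic", "mixed")

# sign of (a_g, a_c) per subtype
_QUADRANT_SIGNS = {
    "quiescent": (-1, -1),
    "glycolytic": (+1, -1),
    "cholesterogenic": (-1, +1),
    "mixed": (+1, +1),
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions.

    Cohort sizes mirror a 400/165/195 three-cohort merge (n = 760 total);
    module sizes mirror the 12-gene glycolytic and 8-gene cholesterogenic
    co-expressed modules with 60/17 uncorrelated decoy pathway genes, so the
    clustering stage faces the realistic 72 -> 12 and 25 -> 8 reduction.
    Quadrant priors default to the observed subtype mix (31.1 / 22.2 / 22.5 /
    24.3 % for quiescent / glycolytic / cholesterogenic / mixed). CNV loss
    probabilities for RB1 (25.7% mixed vs 12.7% quiescent) and LRP1B (27.9%
    vs 10.2%) are generator parameters, not reproduced outputs.
    """

    cohort_sizes: tuple[int, ...] = (400, 165, 195)
    cohort_names: tuple[str, ...] = ("cohortA", "cohortB", "cohortC")
    n_background_genes: int = 2000
    module_size_g: int = 12
    module_size_c: int = 8
    n_decoy_g: int = 60
    n_decoy_c: int = 17
    # decoy pathway genes co-express in their own blocks (as real pathway genes
    # do) but the block factors are independent of the subtype activities
    n_decoy_blocks_g: int = 5
    n_decoy_blocks_c: int = 3
    decoy_loading: float = 0.5
    loading: float = 1.0  # lambda: module-gene loading on the latent activity
    noise_sd: float = 1.0  # sigma: residual sd on log2 scale
    # cohort-level batch model (ComBat family): additive per-gene effects
    # gamma_bg ~ N(batch_shift[b], batch_gene_sd) and scales delta_b
    batch_shift: tuple[float, ...] = (0.0, 1.5, -1.0)
    batch_scale: tuple[float, ...] = (1.0, 1.3, 0.8)
    batch_gene_sd: float = 1.0
    # latent quadrant activities
    quadrant_priors: tuple[float, ...] = (0.311, 0.222, 0.225, 0.243)
    activity_mean: float = 2.0
    activity_sd: float = 1.0
    # survival: exponential PH, hazard = baseline_hazard * exp(log_hr[subtype])
    baseline_hazard: float = 0.02  # events per month for quiescent
    log_hr: dict = field(
        default_factory=lambda: {
            "quiescent": 0.0,
            "glycolytic": float(np.log(1.5)),
            "cholesterogenic": float(np.log(1.2)),
            "mixed": float(np.log(2.0)),
        }
    )
    censor_window: tuple[float, float] = (6.0, 120.0)  # months, uniform
    # CNV loss probabilities per subtype for the two planted loss genes
    cnv_loss_rates: dict = field(
        default_factory=lambda: {
            "RB1": {
                "quiescent": 0.127,
                "glycolytic": 0.19,
                "cholesterogenic": 0.19,
                "mixed": 0.257,
            },
            "LRP1B": {
                "quiescent": 0.102,
                "glycolytic": 0.19,
                "cholesterogenic": 0.19,
                "mixed": 0.279,
            },
        }
    )
    module_cnv_loss: float = 0.05
    module_cnv_gain: float = 0.15  # gains more common than losses for module genes
    snv_rate: float = 0.02
    # immune mixtures
    n_cell_types: int = 5
    n_marker_genes: int = 60
    dirichlet_alpha: float = 1.0
    mixture_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (
            *self.cohort_sizes,
            self.n_background_genes,
            self.module_size_g,
            self.module_size_c,
            self.n_cell_types,
            self.n_marker_genes,
        )
        if any(s < 1 for s in sizes):
            raise ConfigError("all sizes must be >= 1")
        if self.noise_sd <= 0 or self.activity_sd <= 0:
            raise ConfigError("noise_sd and activity_sd must be > 0")
        if any(d <= 0 for d in self.batch_scale):
            raise ConfigError("batch scales must be > 0")
        if len(self.cohort_sizes) != len(self.cohort_names):
            raise ConfigError("cohort_sizes and cohort_names length mismatch")
        if len(self.batch_shift) != len(self.cohort_sizes) or len(self.batch_scale) != len(
            self.cohort_sizes
        ):
            raise ConfigError("batch parameters must match the number of cohorts")
        pri = np.asarray(self.quadrant_priors, dtype=float)
        # rounded percentage tables may sum to e.g. 100.1%; renormalize small drift
        if pri.shape != (4,) or (pri < 0).any() or abs(pri.sum() - 1.0) > 0.01:
            raise ConfigError("quadrant_priors must be 4 non-negative values summing to 1")
        self.quadrant_priors = tuple(pri / pri.sum())
        if np.asarray(self.dirichlet_alpha).min() <= 0:
            raise ConfigError("dirichlet_alpha must be > 0")
        for gene, rates in self.cnv_loss_rates.items():
            for p in rates.values():
                if not 0 <= p <= 1:
                    raise ConfigError(f"CNV loss probability out of [0,1] for {gene}")
        if self.n_marker_genes > self.n_background_genes:
            raise ConfigError("marker genes must fit inside the background gene count")

    # gene naming -----------------------------------------------------------

    @property
    def module_g_genes(self) -> list[str]:
        return [f"GLY{i:02d}" for i in range(1, self.module_size_g + 1)]

    @property
    def module_c_genes(self) -> list[str]:
        return [f"CHOL{i:02d}" for i in range(1, self.module_size_c + 1)]

    @property
    def decoy_g_genes(self) -> list[str]:
        return [f"GLYD{i:02d}" for i in range(1, self.n_decoy_g + 1)]

    @property
    def decoy_c_genes(self) -> list[str]:
        return [f"CHOLD{i:02d}" for i in range(1, self.n_decoy_c + 1)]

    @property
    def marker_genes(self) -> list[str]:
        return [f"IMM{i:03d}" for i in range(1, self.n_marker_genes + 1)]

    #: background genes given biological names so downstream examples
    #: (PDK screen, CNV comparisons) address realistic ids
    NAMED_BACKGROUND = ("PDK1", "PDK2", "PDK3", "PDK4", "PIK3CA", "RB1", "LRP1B", "MPC1", "MPC2")

    @property
    def background_genes(self) -> list[str]:
        named = list(self.NAMED_BACKGROUND)
        n_plain = self.n_background_genes - self.n_marker_genes - len(named)
        if n_plain < 0:
            raise ConfigError("background gene count too small for named + marker genes")
        plain = [f"BG{i:04d}" for i in range(1, n_plain + 1)]
        return named + self.marker_genes + plain

    @property
    def all_genes(self) -> list[str]:
        return (
            self.background_genes
            + self.module_g_genes
            + self.decoy_g_genes
            + self.module_c_genes
            + self.decoy_c_genes
        )

    def pathway_sets(self) -> GeneSetCollection:
        """The two input pathway gene lists handed to the clustering stage."""
        return GeneSetCollection(
            {
                "GLYCOLYSIS": ("glycolysis pathway", self.module_g_genes + self.decoy_g_genes),
                "CHOLESTEROL_BIOSYNTHESIS": (
                    "cholesterol biosynthesis pathway",
                    self.module_c_genes + self.decoy_c_genes,
                ),
            }
        )


@dataclass
class GroundTruth:
    """Truth channel for recovery tests."""

    activities: pd.DataFrame  # per sample: a_g, a_c, label
    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    module_g: list[str]
    module_c: list[str]

    def __post_init__(self) -> None:
        lab = self.activities["label"]
        sign_ok = True
        for s, (sg, sc) in _QUADRANT_SIGNS.items():
            sub = self.activities[lab == s]
            sign_ok &= bool((np.sign(sub["a_g"]) == sg).all() and (np.sign(sub["a_c"]) == sc).all())
        if not sign_ok:
            raise ConfigError("ground-truth labels inconsistent with activity signs")
        if not np.allclose(self.fractions.sum(axis=1), 1.0):
            raise ConfigError("ground-truth fractions must sum to 1 per sample")

    @property
    def labels(self) -> pd.Series:
        return self.activities["label"]


def _draw_truncated_activities(rng, labels: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Rejection-sample (a_g, a_c) ~ N(quadrant mean, sd^2 I) truncated to quadrant signs."""
    n = len(labels)
    out = np.empty((n, 2))
    signs = np.array([_QUADRANT_SIGNS[s] for s in labels], dtype=float)
    means = signs * cfg.activity_mean
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(means[todo], cfg.activity_sd)
        ok = (np.sign(draw) == signs[todo]).all(axis=1)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _make_signature(rng, cfg: SimulationConfig) -> pd.DataFrame:
    """Block-structured marker signature: each cell type upweights its own block."""
    genes, k = cfg.marker_genes, cfg.n_cell_types
    S = rng.uniform(0.5, 1.5, size=(len(genes), k))
    blocks = np.array_split(np.arange(len(genes)), k)
    for j, idx in enumerate(blocks):
        S[idx, j] += rng.uniform(6.0, 10.0, size=len(idx))
    return pd.DataFrame(S, index=genes, columns=[f"celltype{j + 1}" for j in range(k)])


def simulate_cohorts(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ExpressionMatrix, ClinicalTable, VariantTable, GroundTruth, pd.DataFrame]:
    """Generate one merged multi-cohort dataset.

    Returns (expression, clinical, variants, truth, signature_matrix). The
    expression model per gene g and sample s in batch b is

        X[g, s] = mu_g + lambda * a_g(s) * 1[g in module_g]
                       + lambda * a_c(s) * 1[g in module_c]
                       + (S @ f_s)[g] * 1[g marker]
                       + gamma_bg + delta_b * eps,   eps ~ N(0, sigma^2),

    with a handful of named background genes carrying partial loadings
    (PDK1-3 on a_g, PIK3CA on both, PDK4/MPC2 negatively on a_g) so that the
    correlation-screen and group-comparison stages see realistic structure.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    genes = cfg.all_genes
    n_genes = len(genes)
    samples, cohorts = [], []
    for name, size in zip(cfg.cohort_names, cfg.cohort_sizes):
        samples += [f"{name}_S{i:04d}" for i in range(1, size + 1)]
        cohorts += [name] * size
    n = len(samples)
    cohort = pd.Series(cohorts, index=samples, name="cohort")

    labels = rng.choice(SUBTYPES, size=n, p=np.asarray(cfg.quadrant_priors, dtype=float))
    act = _draw_truncated_activities(rng, labels, cfg)
    a_g, a_c = act[:, 0], act[:, 1]

    gi = {g: i for i, g in enumerate(genes)}
    mu = rng.normal(7.0, 2.0, size=n_genes)
    X = np.tile(mu[:, None], (1, n))

    lam = cfg.loading
    for g in cfg.module_g_genes:
        X[gi[g]] += lam * a_g
    for g in cfg.module_c_genes:
        X[gi[g]] += lam * a_c
    # decoy blocks: shared within-block factors, independent of (a_g, a_c)
    for decoys, n_blocks in (
        (cfg.decoy_g_genes, cfg.n_decoy_blocks_g),
        (cfg.decoy_c_genes, cfg.n_decoy_blocks_c),
    ):
        for block in np.array_split(np.arange(len(decoys)), n_blocks):
            factor = rng.normal(0.0, 1.0, size=n)
            for bi in block:
                X[gi[decoys[bi]]] += cfg.decoy_loading * factor

    # partial loadings for named pyruvate-fate regulators
    partial = {"PDK1": 0.8, "PDK2": 0.8, "PDK3": 0.8, "PDK4": -0.3, "MPC2": -0.3}
    for g, w in partial.items():
        X[gi[g]] += w * lam * a_g
    X[gi["PIK3CA"]] += lam * (0.35 * a_g + 0.45 * a_c)

    signature = _make_signature(rng, cfg)
    alpha = np.broadcast_to(
        np.asarray(cfg.dirichlet_alpha, dtype=float), (cfg.n_cell_types,)
    ).copy()
    fractions = rng.dirichlet(alpha, size=n)
    marker_idx = [gi[g] for g in cfg.marker_genes]
    X[marker_idx, :] += cfg.mixture_scale * (signature.to_numpy() @ fractions.T)

    # cohort-level batch effects + scaled noise
    for b, name in enumerate(cfg.cohort_names):
        cols = np.flatnonzero(cohort.to_numpy() == name)
        gamma_bg = rng.normal(cfg.batch_shift[b], cfg.batch_gene_sd, size=n_genes)
        eps = rng.normal(0.0, cfg.noise_sd, size=(n_genes, cols.size))
        X[:, cols] += gamma_bg[:, None] + cfg.batch_scale[b] * eps

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), cohort)

    # survival: exponential PH with uniform administrative censoring
    hr = np.array([np.exp(cfg.log_hr[s]) for s in labels])
    t_event = rng.exponential(1.0 / (cfg.baseline_hazard * hr))
    t_cens = rng.uniform(*cfg.censor_window, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)

    # clinical covariates with mild subtype links
    p_basal = {"quiescent": 0.2, "glycolytic": 0.6, "cholesterogenic": 0.25, "mixed": 0.65}
    p_high_grade = {"quiescent": 0.5, "glycolytic": 0.75, "cholesterogenic": 0.6, "mixed": 0.85}
    stem_mean = {"quiescent": 0.30, "glycolytic": 0.45, "cholesterogenic": 0.40, "mixed": 0.55}
    basal = rng.random(n) < np.array([p_basal[s] for s in labels])
    grade = np.where(rng.random(n) < [p_high_grade[s] for s in labels], "high", "low")
    stage_p = {
        "quiescent": (0.5, 0.35, 0.15),
        "glycolytic": (0.35, 0.4, 0.25),
        "cholesterogenic": (0.45, 0.35, 0.2),
        "mixed": (0.25, 0.4, 0.35),
    }
    stage = np.array([rng.choice(["II", "III", "IV"], p=stage_p[s]) for s in labels])
    conc = 20.0
    sm = np.array([stem_mean[s] for s in labels])
    stemness = rng.beta(sm * conc, (1 - sm) * conc)
    clin = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age": rng.normal(68.0, 10.0, size=n).round(1),
            "gender": rng.choice(["male", "female"], size=n, p=[0.75, 0.25]),
            "grade": grade,
            "stage": stage,
            "molecular_phenotype": np.where(basal, "basal", "luminal"),
            "stemness_index": stemness,
        },
        index=pd.Index(samples, name="sample"),
    )
    # immunotherapy response only observed in the third (trial-like) cohort
    resp = pd.Series(pd.NA, index=samples, dtype=object)
    trial = cohort == cfg.cohort_names[-1]
    resp[trial] = rng.choice(["responder", "non-responder"], size=int(trial.sum()), p=[0.25, 0.75])
    clin["response"] = resp
    clinical = ClinicalTable(clin)

    # variants: CNV calls for module genes + named loss genes; rare SNVs
    cnv_genes = cfg.module_g_genes + cfg.module_c_genes + list(cfg.NAMED_BACKGROUND)
    calls = np.full((len(cnv_genes), n), "neutral", dtype=object)
    for i, g in enumerate(cnv_genes):
        if g in cfg.cnv_loss_rates:
            p_loss = np.array([cfg.cnv_loss_rates[g][s] for s in labels])
            p_gain = np.full(n, 0.05)
        else:
            p_loss = np.full(n, cfg.module_cnv_loss)
            p_gain = np.full(n, cfg.module_cnv_gain)
        u = rng.random(n)
        calls[i, u < p_loss] = "loss"
        calls[i, (u >= p_loss) & (u < p_loss + p_gain)] = "gain"
    cnv = pd.DataFrame(calls, index=cnv_genes, columns=samples)
    snv = set()
    for g in cnv_genes:
        hit = rng.random(n) < cfg.snv_rate
        for s in np.asarray(samples)[hit]:
            snv.add((g, str(s), "missense"))
    variants = VariantTable(snv, cnv)

    truth = GroundTruth(
        activities=pd.DataFrame(
            {"a_g": a_g, "a_c": a_c, "label": labels}, index=pd.Index(samples, name="sample")
        ),
        fractions=pd.DataFrame(fractions, index=samples, columns=signature.columns),
        module_g=cfg.module_g_genes,
        module_c=cfg.module_c_genes,
    )
    return expr, clinical, variants, truth, signature


def simulate_mixture(
    signature: pd.DataFrame,
    n_mix: int,
    dirichlet_alpha=1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw bulk mixtures = signature @ fractions + Gaussian noise.

    Fractions are Dirichlet(alpha) rows summing to 1. Returns
    (mixtures genes x samples, fractions samples x cell types).
    """
    if signature.shape[1] < 2:
        raise ConfigError("signature needs >= 2 cell types")
    if signature.shape[0] < 10:
        raise ConfigError("signature needs >= 10 marker genes")
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (signature.shape[1],))
    if (alpha <= 0).any():
        raise ConfigError("dirichlet_alpha must be > 0")
    rng = np.random.default_rng(seed)
    F = rng.dirichlet(alpha.copy(), size=n_mix)
    M = signature.to_numpy() @ F.T
    if noise_sd > 0:
        M = M + rng.normal(0.0, noise_sd, size=M.shape)
    cols = [f"mix{i + 1:03d}" for i in range(n_mix)]
    mixtures = pd.DataFrame(M, index=signature.index, columns=cols)
    fractions = pd.DataFrame(F, index=cols, columns=signature.columns)
    return mixtures, fractions
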