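"""Quadrant metabolic subtyping from module median Z-scores.

Each sample gets a glycolytic score (median Z across the co-expressed
glycolytic module genes) and a cholesterogenic score (median Z across the
cholesterogenic module), computed on the same gene-wise Z-scores used for
clustering. The four subtypes partition the score plane with inclusive zero
boundaries:

    quiescent        score_g <= 0 and score_c <= 0
    glycolytic       score_g  > 0 and score_c <= 0
    cholesterogenic  score_g <= 0 and score_c  > 0
    mixed            score_g  > 0 and score_c  > 0
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix

__all__ = ["SUBTYPE_LABELS", "SubtypeAssignment", "score_samples", "assign_quadrant", "subtype_cohort"]

SUBTYPE_LABELS = ("quiescent", "glycolytic", "cholesterogenic", "mixed")


@dataclass
class SubtypeAssignment:
    """Per-sample scores and quadrant label, plus the cohort proportion table."""

    table: pd.DataFrame  # index sample; columns score_g, score_c, label
    proportions: pd.Series  # percent per label, 1 decimal

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def score_samples(Z: ExpressionMatrix, module_g, module_c) -> pd.DataFrame:
    """Median module Z-score per sample for both modules.

    ``Z`` rows must already be gene-wise Z-scores; even-sized modules use the
    mean of the two central order statistics (the standard median).
    """
    missing = [g for g in [*module_g, *module_c] if g not in Z.values.index]
    if missing:
        raise ValidationError(f"module gene(s) absent from matrix: {missing}")
    score_g = Z.values.loc[list(module_g)].median(axis=0)
    score_c = Z.values.loc[list(module_c)].median(axis=0)
    return pd.DataFrame({"score_g": score_g, "score_c": score_c})


def assign_quadrant(score_g: float, score_c: float) -> str:
    """Label one sample from its score pair; boundary 0 goes to the <=0 side."""
    if not (np.isfinite(score_g) and np.isfinite(score_c)):
        raise ValidationError(f"non-finite scores: ({score_g}, {score_c})")
    if score_g > 0:
        return "mixed" if score_c > 0 else "glycolytic"
    return "cholesterogenic" if score_c > 0 else "quiescent"


def subtype_cohort(Z: ExpressionMatrix, module_g, module_c) -> SubtypeAssignment:
    """Score and label every sample; proportions reported in percent (1 dp)."""
    scores = score_samples(Z, module_g, module_c)
    labels = [assign_quadrant(g, c) for g, c in zip(scores["score_g"], scores["score_c"])]
    table = scores.assign(label=labels)
    counts = table["label"].value_counts().reindex(SUBTYPE_LABELS, fill_value=0)
    proportions = (100.0 * counts / len(table)).round(1)
    proportions.name = "percent"
    return SubtypeAssignment(table=table, proportions=proportions)
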