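"""Confidence-interval classification against the synonymous distribution,
human-variant annotation, and two-sample distribution comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .variant_model import VariantKey

__all__ = [
    "ClassThresholds",
    "CLASS_LABELS",
    "synonymous_thresholds",
    "classify_variant",
    "classify_table",
    "annotate_human_variants",
    "compare_distributions",
]

CLASS_LABELS = ("low", "possibly_low", "possibly_WT-like", "WT-like", "high")


@dataclass(frozen=True)
class ClassThresholds:
    """5th / 95th percentiles of the synonymous score distribution."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if self.t_low > self.t_high:
            raise ValueError("t_low must not exceed t_high")


def synonymous_thresholds(
    scores: pd.DataFrame, score_column: str = "score"
) -> ClassThresholds:
    """Linear-interpolated 5th/95th percentiles of scored synonymous variants."""
    syn = scores.loc[
        (scores["mut_class"] == "synonymous") & scores[score_column].notna(),
        score_column,
    ].to_numpy(float)
    if len(syn) == 0:
        raise ValueError("no scored synonymous variants to set thresholds")
    if len(syn) < 20:
        warnings.warn(
            f"only {len(syn)} synonymous scores; thresholds will be unstable",
            stacklevel=2,
        )
    t_low, t_high = np.percentile(syn, [5, 95])
    return ClassThresholds(float(t_low), float(t_high))


def classify_variant(
    score: float, ci_lower: float, ci_upper: float, thresholds: ClassThresholds
) -> str:
    """Five-way call from a score and its 95% CI.

    Order of decision: low (score and upper CI below t_low), possibly_low
    (score below t_low only), high (score above t_high with lower CI above
    t_low), WT-like (lower CI above t_low), else possibly_WT-like. Note the
    "high" rule deliberately tests the lower CI against the *lower*
    threshold. Ties at a threshold resolve toward the WT-like side.
    """
    if not np.isfinite(score):
        raise ValueError("cannot classify an undefined score")
    t_low, t_high = thresholds.t_low, thresholds.t_high
    if score < t_low and ci_upper < t_low:
        return "low"
    if score < t_low:
        return "possibly_low"
    if score > t_high and ci_lower >= t_low:
        return "high"
    if ci_lower >= t_low:
        return "WT-like"
    return "possibly_WT-like"


def classify_table(
    scores: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    score_column: str = "score",
) -> pd.DataFrame:
    """Add a ``class`` column; unscored rows get an empty label and a reason."""
    if thresholds is None:
        thresholds = synonymous_thresholds(scores, score_column)
    out = scores.copy()
    labels = []
    for score, lo, hi in zip(
        out[score_column], out["CI_lower"], out["CI_upper"]
    ):
        if not np.isfinite(score):
            labels.append("")
        else:
            labels.append(classify_variant(score, lo, hi, thresholds))
    out["class"] = labels
    return out


def annotate_human_variants(
    curated: pd.DataFrame,
    classified_scores: pd.DataFrame,
    variant_column: str = "variant",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join a curated variant list to scores/classes.

    Returns (annotated table, histogram). The annotated table keeps every
    curated row, adding score/class columns (NaN/empty when the variant was
    not scored) plus ``parse_error`` and ``annotated`` flags. The histogram
    is a (mut_class x class) cross-tabulation of annotated rows.
    """
    lookup = classified_scores.set_index("variant")
    rows = []
    for _, row in curated.iterrows():
        token = str(row[variant_column]).strip()
        entry = dict(row)
        entry["parse_error"] = False
        try:
            key = VariantKey.from_token(token)
            entry["mut_class"] = key.mut_class.value
        except ValueError:
            entry["parse_error"] = True
            entry["mut_class"] = ""
        entry["score"] = np.nan
        entry["class"] = ""
        if not entry["parse_error"] and token in lookup.index:
            hit = lookup.loc[token]
            entry["score"] = hit["score"]
            entry["class"] = hit["class"]
        entry["annotated"] = bool(entry["class"])
        rows.append(entry)
    annotated = pd.DataFrame(rows)
    subset = annotated[annotated["annotated"]]
    histogram = (
        pd.crosstab(subset["mut_class"], subset["class"])
        if len(subset)
        else pd.DataFrame()
    )
    return annotated, histogram


def compare_distributions(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 finite values in each sample")
    result = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(result.statistic), float(min(result.pvalue, 1.0))
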