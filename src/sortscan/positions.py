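"""Position-level analyses: hierarchical clustering of substitution-score
vectors, dataset-wide score rescaling, per-variant specific activity, and
calling of functionally constrained (active-site-like) positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .variant_model import STOP

__all__ = [
    "position_score_matrix",
    "pairwise_complete_distances",
    "cluster_positions",
    "rescale_scores",
    "specific_activity",
    "build_position_table",
    "constrained_positions",
]

SUBSTITUTION_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY") + (STOP,)


def position_score_matrix(
    scores: pd.DataFrame, score_column: str = "score"
) -> pd.DataFrame:
    """Pivot a variant score table to positions x substitutions (NaN=missing)."""
    sub = scores[scores[score_column].notna()]
    matrix = sub.pivot_table(
        index="position", columns="alt_aa", values=score_column, aggfunc="mean"
    )
    return matrix.reindex(columns=[a for a in SUBSTITUTION_ORDER if a in matrix])


def pairwise_complete_distances(matrix: np.ndarray) -> np.ndarray:
    """Euclidean distance over shared (both-present) columns, scaled by
    sqrt(n_total / n_shared) to stay comparable across missingness patterns.

    Raises if any pair of rows shares no scored column.
    """
    x = np.asarray(matrix, dtype=float)
    n, m = x.shape
    present = np.isfinite(x)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"rows {i} and {j} share no scored substitutions; "
                    "distance undefined"
                )
            diff = x[i, shared] - x[j, shared]
            d = np.sqrt((diff @ diff) * (m / n_shared))
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass
class ClusterResult:
    labels: np.ndarray  # group id (1..k) per row
    leaf_order: np.ndarray  # dendrogram leaf order (row indices)
    linkage: np.ndarray  # scipy linkage matrix
    positions: np.ndarray  # row identities


def cluster_positions(
    matrix: pd.DataFrame | np.ndarray,
    k: int = 4,
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of position score vectors, cut into k groups."""
    if isinstance(matrix, pd.DataFrame):
        positions = matrix.index.to_numpy()
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        positions = np.arange(values.shape[0])
    usable = np.isfinite(values).any(axis=1)
    if usable.sum() < k:
        raise ValueError(f"need at least k={k} positions with scores")
    values = values[usable]
    positions = positions[usable]

    dist = pairwise_complete_distances(values)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=method)
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    leaf_order = np.asarray(hierarchy.leaves_list(linkage))
    return ClusterResult(labels, leaf_order, linkage, positions)


def rescale_scores(values: np.ndarray | pd.Series) -> np.ndarray:
    """Affine map sending the dataset minimum to 0 and maximum to 1.

    NaNs pass through; requires at least two distinct finite values.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if len(np.unique(finite)) < 2:
        raise ValueError("rescaling needs at least two distinct values")
    lo, hi = finite.min(), finite.max()
    return (arr - lo) / (hi - lo)


def specific_activity(
    rescaled_activity: np.ndarray | float,
    rescaled_abundance: np.ndarray | float,
    eps: float = 1e-6,
) -> np.ndarray | float:
    """Ratio of rescaled activity to rescaled abundance; NaN (undefined)
    when abundance is below ``eps`` or either input is missing."""
    a = np.asarray(rescaled_activity, dtype=float)
    b = np.asarray(rescaled_abundance, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(
            np.isfinite(a) & np.isfinite(b) & (b > eps), a / b, np.nan
        )
    if ratio.ndim == 0:
        return float(ratio)
    return ratio


def build_position_table(
    abundance: pd.DataFrame,
    activity: pd.DataFrame,
    score_column: str = "score",
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Positional summary joining abundance and activity variant tables.

    Rescaling is dataset-wide (each table's own min/max, nonsense and
    synonymous included). Specific activity is computed per variant, then
    summarized as the positional median over defined ratios.
    """
    ab = abundance[abundance[score_column].notna()][
        ["variant", "position", "mut_class", score_column]
    ].rename(columns={score_column: "abundance"})
    ac = activity[activity[score_column].notna()][
        ["variant", "position", "mut_class", score_column]
    ].rename(columns={score_column: "activity"})
    ab["rescaled_abundance"] = rescale_scores(ab["abundance"])
    ac["rescaled_activity"] = rescale_scores(ac["activity"])

    merged = ab.merge(
        ac[["variant", "activity", "rescaled_activity"]], on="variant", how="outer"
    )
    merged["position"] = merged["position"].astype("Int64")
    merged["specific_activity"] = specific_activity(
        merged["rescaled_activity"].to_numpy(float),
        merged["rescaled_abundance"].to_numpy(float),
        eps=eps,
    )

    def summarize(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "median_abundance": group["abundance"].median(),
                "median_activity": group["activity"].median(),
                "rescaled_abundance": group["rescaled_abundance"].median(),
                "rescaled_activity": group["rescaled_activity"].median(),
                "specific_activity": group["specific_activity"].median(),
                "n_abundance_variants": int(group["abundance"].notna().sum()),
                "n_activity_variants": int(group["activity"].notna().sum()),
            }
        )

    table = (
        merged.groupby("position").apply(summarize, include_groups=False).reset_index()
    )
    table["position"] = table["position"].astype(int)
    return table.sort_values("position").reset_index(drop=True)


def constrained_positions(
    position_table: pd.DataFrame,
    quantile: float = 0.125,
    min_variants: int = 4,
    filter_first: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Positions in the lowest ``quantile`` of median specific activity with
    at least ``min_variants`` activity-scored variants.

    Default order computes the quantile threshold over all positions with a
    defined median, then applies the variant-count filter; ``filter_first``
    restricts the threshold computation to well-sampled positions instead.
    Returns (table with a boolean ``constrained`` column, threshold used).
    """
    table = position_table.copy()
    defined = table["specific_activity"].notna()
    if not defined.any():
        raise ValueError("no positions with a defined median specific activity")
    pool = defined & (
        (table["n_activity_variants"] >= min_variants) if filter_first else True
    )
    threshold = float(
        np.percentile(table.loc[pool, "specific_activity"], 100 * quantile)
    )
    table["constrained"] = (
        defined
        & (table["specific_activity"] <= threshold)
        & (table["n_activity_variants"] >= min_variants)
    )
    return table, threshold
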