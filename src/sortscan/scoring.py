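"""Sort-seq score computation.

Per replicate: per-bin frequencies -> frequency/representation filters ->
bin-weighted averages -> min-max normalization anchored at the nonsense
median (0) and synonymous median (1). Replicate scores are then averaged
into an experiment-wide score with SD, SE and a normal-theory 95% CI.

The per-replicate normalization pins the anchor medians exactly within each
replicate; by default the aggregated scores are re-anchored once more so the
experiment-wide synonymous and nonsense medians are exactly 1 and 0 as well
(an affine transform that rescales SD/SE/CI consistently).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountTensor
from .variant_model import MutClass, VariantKey

__all__ = [
    "ScoringParams",
    "bin_frequencies",
    "filter_replicate",
    "weighted_average",
    "normalize_replicate",
    "aggregate_replicates",
    "score_experiment",
]


@dataclass(frozen=True)
class ScoringParams:
    bin_weights: tuple[float, float, float, float] = (0.25, 0.5, 0.75, 1.0)
    f_expt_min: int = 2
    f_freq_min: float = 1e-4
    ci_z: float = 1.96
    renormalize_final: bool = True

    def __post_init__(self) -> None:
        w = np.asarray(self.bin_weights, float)
        if len(w) != 4 or not np.all(np.diff(w) > 0):
            raise ValueError("bin_weights must be 4 strictly increasing values")
        if not 0 < self.f_freq_min < 1:
            raise ValueError("f_freq_min must lie in (0, 1)")
        if self.f_expt_min < 1:
            raise ValueError("f_expt_min must be >= 1")


def bin_frequencies(counts: np.ndarray) -> np.ndarray:
    """Counts (R, 4, V) -> frequencies, each (replicate, bin) summing to 1."""
    counts = np.asarray(counts)
    totals = counts.sum(axis=-1, keepdims=True)
    zero = np.argwhere(totals[..., 0] == 0)
    if zero.size:
        r, b = zero[0]
        raise ValueError(f"zero total count in replicate {r}, bin {b + 1}")
    return counts / totals


def filter_replicate(freqs: np.ndarray, params: ScoringParams) -> np.ndarray:
    """Per-(replicate, variant) inclusion mask: the variant's frequency summed
    over the 4 bins must reach ``f_freq_min`` in that replicate."""
    return freqs.sum(axis=1) >= params.f_freq_min


def weighted_average(
    freqs: np.ndarray, weights: Sequence[float] = (0.25, 0.5, 0.75, 1.0)
) -> np.ndarray:
    """Bin-weighted mean w = sum_b weight_b * f_b / sum_b f_b.

    ``freqs`` carries bins on the last axis; all-zero rows yield NaN.
    """
    freqs = np.asarray(freqs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = freqs.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (freqs * weights).sum(axis=-1) / total
    return np.where(total > 0, w, np.nan)


def _median(values: np.ndarray) -> float:
    return float(np.median(values))


def normalize_replicate(
    w: np.ndarray,
    mut_classes: Sequence[str],
    included: np.ndarray | None = None,
) -> np.ndarray:
    """Min-max normalize one replicate's weighted averages to the included
    nonsense median (-> 0) and synonymous median (-> 1)."""
    w = np.asarray(w, dtype=float)
    classes = np.asarray(mut_classes)
    if included is None:
        included = np.ones(len(w), dtype=bool)
    usable = included & np.isfinite(w)

    non = w[usable & (classes == MutClass.NONSENSE.value)]
    syn = w[usable & (classes == MutClass.SYNONYMOUS.value)]
    if len(non) == 0 or len(syn) == 0:
        raise ValueError("replicate lacks an included nonsense or synonymous anchor")
    m0, m1 = _median(non), _median(syn)
    if m1 <= m0:
        raise ValueError(
            f"synonymous median ({m1:.4g}) must exceed nonsense median ({m0:.4g})"
        )
    return (w - m0) / (m1 - m0)


def aggregate_replicates(
    replicate_scores: np.ndarray, params: ScoringParams
) -> pd.DataFrame:
    """Average per-replicate scores (R, V; NaN = excluded) into final scores.

    Rows observed in fewer than ``f_expt_min`` replicates get NaN score and
    an exclusion reason. SD uses the n-1 denominator; SE = SD/sqrt(n);
    CI = mean +/- ci_z * SE.
    """
    scores = np.asarray(replicate_scores, dtype=float)
    n = np.isfinite(scores).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(scores), scores, np.nan), axis=0)
        sd = np.full(scores.shape[1], np.nan)
        multi = n > 1
        if multi.any():
            sd[multi] = np.nanstd(scores[:, multi], axis=0, ddof=1)
    ok = n >= params.f_expt_min
    se = sd / np.sqrt(np.where(n > 0, n, 1))
    frame = pd.DataFrame(
        {
            "score": np.where(ok, mean, np.nan),
            "SD": np.where(ok, sd, np.nan),
            "SE": np.where(ok, se, np.nan),
            "n_reps": n,
        }
    )
    frame["CI_lower"] = frame["score"] - params.ci_z * frame["SE"]
    frame["CI_upper"] = frame["score"] + params.ci_z * frame["SE"]
    frame["exclusion_reason"] = np.where(
        ok, "", f"observed in fewer than {params.f_expt_min} replicates"
    )
    return frame


def score_experiment(
    tensor: CountTensor,
    mut_classes: Mapping[str, str] | None = None,
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Full scoring pipeline on a (replicate, bin, variant) count tensor.

    ``mut_classes`` maps variant token -> mutation class; when omitted the
    classes are parsed from the variant tokens themselves. Returns one row
    per variant (excluded variants retained with a reason), with per-variant
    identity columns parsed from the token.
    """
    if params is None:
        params = ScoringParams()
    variants = tensor.variants
    if mut_classes is None:
        classes = [VariantKey.from_token(v).mut_class.value for v in variants]
    else:
        classes = [mut_classes[v] for v in variants]
    classes_arr = np.asarray(classes)

    freqs = bin_frequencies(tensor.counts)  # (R, 4, V)
    included = filter_replicate(freqs, params)  # (R, V)
    w = weighted_average(np.moveaxis(freqs, 1, -1), params.bin_weights)  # (R, V)

    norm = np.full_like(w, np.nan)
    for r in range(w.shape[0]):
        norm[r] = normalize_replicate(w[r], classes_arr, included[r])
    norm[~included | ~np.isfinite(w)] = np.nan

    frame = aggregate_replicates(norm, params)
    frame.insert(0, "variant", variants)
    keys = [VariantKey.from_token(v) for v in variants]
    frame.insert(1, "position", [k.position for k in keys])
    frame.insert(2, "wt_aa", [k.wt_aa for k in keys])
    frame.insert(3, "alt_aa", [k.alt_aa for k in keys])
    frame.insert(4, "mut_class", classes)

    if params.renormalize_final:
        frame = _renormalize_final(frame)
    return frame


def _renormalize_final(frame: pd.DataFrame) -> pd.DataFrame:
    """Re-anchor aggregated scores so experiment-wide anchor medians are
    exactly 0 (nonsense) and 1 (synonymous); affine, so SD/SE/CI rescale."""
    scored = frame["score"].notna()
    non = frame.loc[scored & (frame["mut_class"] == MutClass.NONSENSE.value), "score"]
    syn = frame.loc[
        scored & (frame["mut_class"] == MutClass.SYNONYMOUS.value), "score"
    ]
    if len(non) == 0 or len(syn) == 0:
        return frame
    m0, m1 = float(non.median()), float(syn.median())
    if m1 <= m0:
        raise ValueError("inverted anchors in final renormalization")
    scale = m1 - m0
    out = frame.copy()
    for col in ("score", "CI_lower", "CI_upper"):
        out[col] = (out[col] - m0) / scale
    for col in ("SD", "SE"):
        out[col] = out[col] / scale
    return out
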