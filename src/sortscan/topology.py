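"""Sliding-window substitution-class score profiles and per-domain score
distributions for membrane-topology inference.

A width-10 window centered at position p spans residues p-4 .. p+5
(right-heavy, the usual centered rolling convention for even widths). The
profile value is the mean over all pooled variant scores in the window whose
substituted residue belongs to the class (charged or aliphatic by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubstitutionClassSpec",
    "CHARGED_SPEC",
    "ALIPHATIC_SPEC",
    "TopologyModel",
    "windowed_profile",
    "call_low_regions",
    "domain_distributions",
]


@dataclass(frozen=True)
class SubstitutionClassSpec:
    name: str
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("substitution class needs at least one residue")
        if any(len(r) != 1 or not r.isupper() for r in self.residues):
            raise ValueError("residues must be uppercase one-letter codes")


CHARGED_SPEC = SubstitutionClassSpec("charged", frozenset("RKHDE"))
ALIPHATIC_SPEC = SubstitutionClassSpec("aliphatic", frozenset("GAVIL"))

DOMAIN_LABELS = ("cytoplasmic", "TM", "lumenal")


@dataclass(frozen=True)
class TopologyModel:
    """Residue compartment labels defined by TM intervals and loop sides."""

    length: int
    tm_intervals: tuple[tuple[int, int], ...]
    first_loop: str = "cytoplasmic"

    def __post_init__(self) -> None:
        last = 0
        for start, end in self.tm_intervals:
            if start <= last or end < start or end > self.length:
                raise ValueError("tm_intervals must be sorted, disjoint, in range")
            last = end
        if self.first_loop not in ("cytoplasmic", "lumenal"):
            raise ValueError("first_loop must be cytoplasmic or lumenal")

    def labels(self) -> dict[int, str]:
        out = {}
        side = self.first_loop
        other = {"cytoplasmic": "lumenal", "lumenal": "cytoplasmic"}
        pos = 1
        for start, end in self.tm_intervals:
            for p in range(pos, start):
                out[p] = side
            for p in range(start, end + 1):
                out[p] = "TM"
            side = other[side]
            pos = end + 1
        for p in range(pos, self.length + 1):
            out[p] = side
        return out


def windowed_profile(
    scores: pd.DataFrame,
    class_spec: SubstitutionClassSpec,
    protein_length: int,
    window: int = 10,
    score_column: str = "score",
) -> pd.DataFrame:
    """Windowed mean of pooled class-substitution scores per center position.

    Positions whose window leaves [1, protein_length], or whose window holds
    no qualifying score, are omitted. Returns columns
    position / class / windowed_mean / n_scores.
    """
    if window < 1:
        raise ValueError("window must be positive")
    left = (window - 1) // 2  # width 10 -> 4 left, 5 right
    right = window - 1 - left

    # missense only: a synonymous variant whose WT residue is in the class is
    # not a class substitution and would drag windows toward 1
    mask = (
        scores[score_column].notna()
        & scores["alt_aa"].isin(class_spec.residues)
        & (scores["mut_class"] == "missense")
    )
    sub = scores.loc[mask, ["position", score_column]]
    rows = []
    for center in range(1 + left, protein_length - right + 1):
        in_window = sub[
            (sub["position"] >= center - left) & (sub["position"] <= center + right)
        ][score_column]
        if len(in_window) == 0:
            continue
        rows.append(
            {
                "position": center,
                "class": class_spec.name,
                "windowed_mean": float(in_window.mean()),
                "n_scores": int(len(in_window)),
            }
        )
    return pd.DataFrame(rows, columns=["position", "class", "windowed_mean", "n_scores"])


def call_low_regions(
    profile: pd.DataFrame, cutoff: float, min_width: int = 1
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive defined positions with mean < cutoff.

    Gaps in the position grid break runs. ``min_width`` discards runs
    shorter than the given width (single-window dips are usually noise when
    hunting membrane-spanning segments).
    """
    below = profile.loc[profile["windowed_mean"] < cutoff, "position"]
    positions = sorted(int(p) for p in below)
    regions: list[tuple[int, int]] = []
    for p in positions:
        if regions and p == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], p)
        else:
            regions.append((p, p))
    return [r for r in regions if r[1] - r[0] + 1 >= min_width]


def domain_distributions(
    scores: pd.DataFrame,
    topology: TopologyModel,
    score_column: str = "score",
    n_bins: int = 30,
) -> dict[str, dict]:
    """Partition scored missense variants by compartment label.

    Returns per-domain: the score vector, n, median, and a shared-range
    histogram (counts, bin_edges). Scored positions missing from the
    topology are an error.
    """
    labels = topology.labels()
    sub = scores[(scores["mut_class"] == "missense") & scores[score_column].notna()]
    unlabeled = sorted(set(sub["position"]) - set(labels))
    if unlabeled:
        raise ValueError(f"positions missing from topology model: {unlabeled[:10]}")

    values = sub[score_column].to_numpy(float)
    edges = (
        np.histogram_bin_edges(values, bins=n_bins) if len(values) else np.array([0, 1])
    )
    out: dict[str, dict] = {}
    for domain in DOMAIN_LABELS:
        dom_positions = {p for p, lab in labels.items() if lab == domain}
        vec = sub.loc[sub["position"].isin(dom_positions), score_column].to_numpy(float)
        counts, _ = np.histogram(vec, bins=edges)
        out[domain] = {
            "scores": vec,
            "n": int(len(vec)),
            "median": float(np.median(vec)) if len(vec) else float("nan"),
            "histogram": (counts, edges),
        }
    return out
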