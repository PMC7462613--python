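"""Local secondary-structure calling from residue-pair coupling strengths.

Helix propensity at residue i sums the couplings to the would-be helical
contacts (i, i+3) and (i, i+4); strand propensity uses (i, i+2). Runs of at
least two consecutive residues above the class cutoff (1.5 for helices,
0.75 for strands) become cores, each extended by one residue per side, and
segments shorter than four residues are discarded. The contact offsets are
configurable because the cutoffs only have meaning relative to a stated
summation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CouplingMatrix",
    "Segment",
    "SSAnnotation",
    "local_ss_scores",
    "call_segments",
    "overlap_enrichment",
]

ALPHA_OFFSETS = (3, 4)
BETA_OFFSETS = (2,)


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric nonnegative L x L coupling strengths; diagonal ignored."""

    strengths: np.ndarray
    first_residue: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.strengths, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValueError("coupling matrix must be symmetric (tol 1e-9)")
        if (arr < 0).any():
            raise ValueError("coupling strengths must be nonnegative")
        object.__setattr__(self, "strengths", arr)

    def __len__(self) -> int:
        return self.strengths.shape[0]

    @classmethod
    def from_pairs(
        cls, pairs: pd.DataFrame, length: int | None = None, first_residue: int = 1
    ) -> "CouplingMatrix":
        """Build from a long table with columns i, j, strength (1-based;
        upper triangle is sufficient)."""
        i = pairs["i"].to_numpy(int) - first_residue
        j = pairs["j"].to_numpy(int) - first_residue
        s = pairs["strength"].to_numpy(float)
        n = length if length is not None else int(max(i.max(), j.max())) + 1
        arr = np.zeros((n, n))
        arr[i, j] = s
        arr[j, i] = s
        return cls(arr, first_residue)


def local_ss_scores(
    matrix: CouplingMatrix,
    alpha_offsets: tuple[int, ...] = ALPHA_OFFSETS,
    beta_offsets: tuple[int, ...] = BETA_OFFSETS,
) -> pd.DataFrame:
    """Per-residue summed coupling strength at helix/strand contact offsets.

    Out-of-range contacts contribute 0. Returns columns
    position / alpha_score / beta_score (positions 1-based).
    """
    arr = matrix.strengths
    n = len(matrix)
    alpha = np.zeros(n)
    beta = np.zeros(n)
    for off in alpha_offsets:
        alpha[: n - off] += arr[np.arange(n - off), np.arange(off, n)]
    for off in beta_offsets:
        beta[: n - off] += arr[np.arange(n - off), np.arange(off, n)]
    return pd.DataFrame(
        {
            "position": np.arange(n) + matrix.first_residue,
            "alpha_score": alpha,
            "beta_score": beta,
        }
    )


@dataclass(frozen=True)
class Segment:
    ss_class: str  # "helix" or "strand"
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def residues(self) -> set[int]:
        return set(range(self.start, self.end + 1))


@dataclass
class SSAnnotation:
    scores: pd.DataFrame
    segments: list[Segment] = field(default_factory=list)

    def per_residue(self) -> pd.DataFrame:
        """Add a ``call`` column (helix/strand/none) to the score table.

        Helix calls take precedence where tracks overlap.
        """
        out = self.scores.copy()
        call = pd.Series("none", index=out.index)
        positions = out["position"]
        for seg in sorted(self.segments, key=lambda s: s.ss_class, reverse=True):
            # strand first, helix second so helix wins overlaps
            call[positions.between(seg.start, seg.end)] = seg.ss_class
        out["call"] = call
        return out


def _runs_above(values: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal runs (0-based, inclusive) of values strictly above cutoff."""
    above = values > cutoff
    runs = []
    start = None
    for idx, flag in enumerate(above):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            runs.append((start, idx - 1))
            start = None
    if start is not None:
        runs.append((start, len(values) - 1))
    return runs


def call_segments(
    scores: pd.DataFrame,
    cutoff_alpha: float = 1.5,
    cutoff_beta: float = 0.75,
    min_core: int = 2,
    extension: int = 1,
    min_len: int = 4,
) -> SSAnnotation:
    """Call helix/strand segments from per-residue scores.

    Cores are runs of >= ``min_core`` consecutive residues above the class
    cutoff; each core is extended by ``extension`` residues per side
    (clipped to the residue range) and kept only if the result reaches
    ``min_len``. The two tracks are called independently.
    """
    positions = scores["position"].to_numpy(int)
    first, last = int(positions[0]), int(positions[-1])
    segments: list[Segment] = []
    for ss_class, column, cutoff in (
        ("helix", "alpha_score", cutoff_alpha),
        ("strand", "beta_score", cutoff_beta),
    ):
        values = scores[column].to_numpy(float)
        extended: list[tuple[int, int]] = []
        for lo, hi in _runs_above(values, cutoff):
            if hi - lo + 1 < min_core:
                continue
            start = int(max(first, positions[lo] - extension))
            end = int(min(last, positions[hi] + extension))
            # extensions may bridge nearby cores; merge overlaps to keep the
            # track's segments disjoint
            if extended and start <= extended[-1][1]:
                extended[-1] = (extended[-1][0], end)
            else:
                extended.append((start, end))
        for start, end in extended:
            if end - start + 1 < min_len:
                continue
            segments.append(Segment(ss_class, start, end))
    segments.sort(key=lambda s: (s.ss_class, s.start))
    return SSAnnotation(scores=scores, segments=segments)


def overlap_enrichment(
    predicted: set[int], reference: set[int], universe: int
) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p-value.

    p = P(X >= overlap) with X ~ Hypergeometric(universe, |reference|,
    |predicted|). Both sets must lie within [1, universe].
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    for name, s in (("predicted", predicted), ("reference", reference)):
        if s and (min(s) < 1 or max(s) > universe):
            raise ValueError(f"{name} set outside [1, {universe}]")
    overlap = len(predicted & reference)
    p = float(stats.hypergeom.sf(overlap - 1, universe, len(reference), len(predicted)))
    return overlap, min(p, 1.0)
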