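"""End-to-end convenience: simulate a binned-sort experiment and score it."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counting import count_barcode_table, merge_counts
from .scoring import ScoringParams, score_experiment
from .synthetic import (
    SimConfig,
    SortResult,
    TruthTable,
    simulate_barcodes,
    simulate_reads,
    simulate_sort,
    simulate_truth,
)

__all__ = ["EndToEndResult", "run_end_to_end"]


@dataclass
class EndToEndResult:
    config: SimConfig
    truth: TruthTable
    barcode_map: pd.DataFrame
    sorts: dict[str, SortResult]
    scores: dict[str, pd.DataFrame]  # assay -> variant score table

    def merged(self, assay: str = "abundance") -> pd.DataFrame:
        """Score table joined to the simulation truth for that assay."""
        truth_cols = self.truth.variants[
            ["variant", "true_abundance", "true_activity", "region_label",
             "is_active_site"]
        ]
        return self.scores[assay].merge(truth_cols, on="variant", how="left")


_ASSAY_COLUMNS = {"abundance": "true_abundance", "activity": "true_activity"}


def run_end_to_end(
    config: SimConfig,
    params: ScoringParams | None = None,
    assays: tuple[str, ...] = ("abundance",),
) -> EndToEndResult:
    """Truth -> sort -> barcoded sequencing -> counting -> scoring."""
    truth = simulate_truth(config)
    barcode_map = simulate_barcodes(truth, config)
    variant_of = dict(zip(barcode_map["barcode"], barcode_map["variant"]))
    classes = dict(zip(truth.variants["variant"], truth.variants["mut_class"]))

    sorts: dict[str, SortResult] = {}
    scores: dict[str, pd.DataFrame] = {}
    for stream, assay in enumerate(assays):
        sort = simulate_sort(truth, config, value_column=_ASSAY_COLUMNS[assay])
        reads = simulate_reads(sort, barcode_map, config, stream=stream)
        tables = []
        for (rep, b), group in reads.groupby(["replicate", "bin"]):
            tables.append(count_barcode_table(group, variant_of, str(rep), int(b)))
        tensor = merge_counts(tables)
        sorts[assay] = sort
        scores[assay] = score_experiment(tensor, classes, params)
    return EndToEndResult(config, truth, barcode_map, sorts, scores)
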