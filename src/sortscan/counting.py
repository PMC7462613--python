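"""Tally barcode reads per (replicate, bin) into variant-level count tables.

Reads are dropped when any base in the barcode span falls below the Phred
quality floor (default Q20). Surviving barcodes must match the barcode map
exactly — no mismatch rescue — and counts for barcodes tagging the same
variant are summed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping
import warnings

import numpy as np
import pandas as pd

__all__ = ["BinCountTable", "count_barcodes", "count_barcode_table", "merge_counts"]


@dataclass
class BinCountTable:
    replicate_id: str
    bin_index: int
    counts: dict[str, int]  # variant token -> reads
    total_reads: int = 0
    n_filtered_quality: int = 0
    n_unmapped_barcodes: int = 0

    def __post_init__(self) -> None:
        if self.bin_index not in (1, 2, 3, 4):
            raise ValueError(f"bin_index must be 1..4, got {self.bin_index}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["variant", "count"]
        )


def _iter_fastq(path: str | Path):
    """Yield (sequence, quality) pairs; raise on truncated records."""
    with open(path) as fh:
        record = []
        index = 0
        for line in fh:
            record.append(line.rstrip("\n"))
            if len(record) == 4:
                header, seq, plus, qual = record
                if not header.startswith("@") or not plus.startswith("+"):
                    raise ValueError(f"malformed FASTQ record {index} in {path}")
                yield seq, qual
                index += 1
                record = []
        if record:
            raise ValueError(
                f"truncated FASTQ record {index} in {path}: "
                f"{len(record)} of 4 lines present"
            )


def count_barcodes(
    fastq_path: str | Path,
    barcode_map: Mapping[str, str],
    replicate_id: str,
    bin_index: int,
    min_quality: int = 20,
    barcode_offset: int = 0,
    barcode_length: int | None = None,
    whole_read_quality: bool = False,
) -> BinCountTable:
    """Count variant reads in one bin's FASTQ file.

    ``barcode_map`` maps barcode sequence -> variant token. The barcode span
    is ``[barcode_offset, barcode_offset + barcode_length)``; by default the
    length is inferred from the map. Quality filtering applies to the
    barcode span only unless ``whole_read_quality`` is set.
    """
    if barcode_length is None:
        lengths = {len(b) for b in barcode_map}
        if len(lengths) > 1:
            raise ValueError("barcode map holds multiple barcode lengths")
        barcode_length = lengths.pop() if lengths else 0

    table = BinCountTable(replicate_id, bin_index, {})
    counts: Counter = Counter()
    end = barcode_offset + barcode_length
    for seq, qual in _iter_fastq(fastq_path):
        table.total_reads += 1
        span_q = qual if whole_read_quality else qual[barcode_offset:end]
        if any(ord(c) - 33 < min_quality for c in span_q):
            table.n_filtered_quality += 1
            continue
        barcode = seq[barcode_offset:end]
        variant = barcode_map.get(barcode)
        if variant is None:
            table.n_unmapped_barcodes += 1
            continue
        counts[variant] += 1
    if table.total_reads == 0:
        warnings.warn(f"empty FASTQ file: {fastq_path}", stacklevel=2)
    table.counts = dict(counts)
    return table


def count_barcode_table(
    barcode_counts: pd.DataFrame,
    barcode_map: Mapping[str, str],
    replicate_id: str,
    bin_index: int,
) -> BinCountTable:
    """Variant-level table from a pre-tallied ``barcode  count`` table."""
    table = BinCountTable(replicate_id, bin_index, {})
    counts: Counter = Counter()
    for barcode, count in zip(barcode_counts["barcode"], barcode_counts["count"]):
        table.total_reads += int(count)
        variant = barcode_map.get(barcode)
        if variant is None:
            table.n_unmapped_barcodes += int(count)
        else:
            counts[variant] += int(count)
    table.counts = dict(counts)
    return table


@dataclass
class CountTensor:
    """Replicate x bin x variant read counts."""

    counts: np.ndarray  # (R, 4, V) int64
    replicates: list[str]
    variants: list[str]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape


def merge_counts(tables: Iterable[BinCountTable]) -> CountTensor:
    """Assemble per-bin tables into a dense (replicate, bin, variant) tensor.

    Variants absent from a table are imputed as zero counts. A duplicate
    (replicate, bin) pair is an error.
    """
    tables = list(tables)
    seen: set[tuple[str, int]] = set()
    for t in tables:
        key = (t.replicate_id, t.bin_index)
        if key in seen:
            raise ValueError(f"duplicate (replicate, bin) table: {key}")
        seen.add(key)

    replicates = sorted({t.replicate_id for t in tables})
    variants = sorted({v for t in tables for v in t.counts})
    rep_idx = {r: i for i, r in enumerate(replicates)}
    var_idx = {v: i for i, v in enumerate(variants)}

    counts = np.zeros((len(replicates), 4, len(variants)), dtype=np.int64)
    for t in tables:
        r = rep_idx[t.replicate_id]
        for variant, c in t.counts.items():
            counts[r, t.bin_index - 1, var_idx[variant]] += c
    return CountTensor(counts, replicates, variants)
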