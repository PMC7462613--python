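"""Plain-text interchange formats (FASTA reference, TSV tables, JSON sidecars)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .counting import BinCountTable
from .variant_model import ProteinReference

SCORE_COLUMNS = [
    "variant",
    "position",
    "wt_aa",
    "alt_aa",
    "mut_class",
    "score",
    "SD",
    "SE",
    "CI_lower",
    "CI_upper",
    "n_reps",
]


def read_reference_fasta(
    path: str | Path, mutagenized_range: tuple[int, int] = (2, 163)
) -> ProteinReference:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return ProteinReference(
        name=rec.id, coding_sequence=str(rec.seq), mutagenized_range=mutagenized_range
    )


def write_barcode_map(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_barcode_map(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"barcode": str, "variant": str})
    missing = {"barcode", "variant"} - set(frame.columns)
    if missing:
        raise ValueError(f"barcode map missing columns: {sorted(missing)}")
    return frame


def barcode_lookup(frame: pd.DataFrame) -> Mapping[str, str]:
    return dict(zip(frame["barcode"], frame["variant"]))


def write_bin_counts(table: BinCountTable, tsv_path: str | Path) -> None:
    """``variant  count`` TSV plus a JSON sidecar with filter counters."""
    tsv_path = Path(tsv_path)
    table.to_frame().to_csv(tsv_path, sep="\t", index=False)
    sidecar = {
        "replicate_id": table.replicate_id,
        "bin_index": table.bin_index,
        "total_reads": table.total_reads,
        "n_filtered_quality": table.n_filtered_quality,
        "n_unmapped_barcodes": table.n_unmapped_barcodes,
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_bin_counts(
    tsv_path: str | Path, replicate_id: str | None = None, bin_index: int | None = None
) -> BinCountTable:
    tsv_path = Path(tsv_path)
    frame = pd.read_csv(tsv_path, sep="\t")
    meta = {}
    sidecar = tsv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    table = BinCountTable(
        replicate_id=replicate_id or meta.get("replicate_id", "R1"),
        bin_index=bin_index or meta.get("bin_index", 1),
        counts=dict(zip(frame["variant"], frame["count"].astype(int))),
        total_reads=meta.get("total_reads", int(frame["count"].sum())),
        n_filtered_quality=meta.get("n_filtered_quality", 0),
        n_unmapped_barcodes=meta.get("n_unmapped_barcodes", 0),
    )
    return table


def write_scores(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SCORE_COLUMNS if c in frame.columns] + [
        c for c in frame.columns if c not in SCORE_COLUMNS
    ]
    frame[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_coupling_pairs(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = {"i", "j", "strength"} - set(frame.columns)
    if missing:
        raise ValueError(f"coupling table missing columns: {sorted(missing)}")
    return frame


def read_topology_tsv(path: str | Path) -> pd.DataFrame:
    """``start  end  label`` intervals."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"start", "end", "label"} - set(frame.columns)
    if missing:
        raise ValueError(f"topology table missing columns: {sorted(missing)}")
    return frame


def read_curated_variants(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "variant" not in frame.columns:
        raise ValueError("curated variant table needs a 'variant' column")
    return frame
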