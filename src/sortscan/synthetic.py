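"""Generative model of a binned-sort (quartile FACS) mutational scanning run.

Produces, from a seeded configuration: a synthetic coding reference, a truth
table of per-variant abundance/activity effects, a barcode map, per-replicate
per-bin cell and read counts, and optionally FASTQ files — everything needed
to exercise the counting/scoring/classification stack without real data.

The effect model is a three-component mixture (WT-like / intermediate / low)
with charged and proline substitutions inside transmembrane segments pushed
into the low component, yielding the characteristic trimodal score
distribution of a membrane-protein scan. Designated "active site" positions
receive low activity but WT-like abundance. Sorting draws per-cell
fluorescence on the score scale and gates each replicate at its own pooled
empirical quartiles; sequencing is multinomial over barcodes in each bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .variant_model import STOP, ProteinReference, VariantKey

__all__ = [
    "EffectModel",
    "SimConfig",
    "TruthTable",
    "SortResult",
    "simulate_reference",
    "simulate_truth",
    "simulate_sort",
    "simulate_barcodes",
    "simulate_reads",
    "write_fastq",
]

CHARGED = frozenset("RKHDE")
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# amino acid -> codons, from the standard table
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(standard_dna_table.stop_codons)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


@dataclass(frozen=True)
class EffectModel:
    """Parameters of the true-effect mixture."""

    mixture_weights: tuple[float, float, float] = (0.60, 0.25, 0.15)
    mixture_means: tuple[float, float, float] = (1.0, 0.5, 0.0)
    mixture_sds: tuple[float, float, float] = (0.10, 0.10, 0.08)
    charged_tmd_low_prob: float = 0.99
    synonymous_sd: float = 0.05
    nonsense_sd: float = 0.05
    n_active_sites: int = 8
    active_site_activity_mean: float = 0.05
    active_site_activity_sd: float = 0.05
    activity_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, float)
        if w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture_weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_positions: int = 162  # residues 2 .. n_positions+1
    tmd_segments: tuple[tuple[int, int], ...] = (
        (12, 29),
        (78, 95),
        (106, 123),
        (134, 151),
    )
    n_missense_per_position: int = 3
    n_synonymous: int = 40
    n_nonsense: int = 25
    n_barcodes_per_variant: float = 3.0  # mean of shifted Poisson (>=1)
    barcode_length: int = 18
    cells_sorted: int = 200_000
    reads_per_bin: int = 1_000_000
    cell_noise_sd: float = 0.35
    n_replicates: int = 4
    library_skew_concentration: float = 5.0
    effect_model: EffectModel = field(default_factory=EffectModel)

    def __post_init__(self) -> None:
        for name in (
            "n_positions",
            "n_barcodes_per_variant",
            "barcode_length",
            "cells_sorted",
            "reads_per_bin",
            "n_replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cell_noise_sd < 0 or self.library_skew_concentration <= 0:
            raise ValueError("invalid noise/skew parameters")
        last = 1
        length = self.n_positions + 1
        for start, end in self.tmd_segments:
            if start <= last or end < start or end > length:
                raise ValueError(
                    f"tmd_segments must be disjoint, sorted, within [2, {length}]"
                )
            last = end

    @property
    def protein_length(self) -> int:
        return self.n_positions + 1

    @property
    def mutagenized_range(self) -> tuple[int, int]:
        return (2, self.protein_length)


@dataclass
class TruthTable:
    """Simulated ground truth: reference plus one row per library variant."""

    reference: ProteinReference
    variants: pd.DataFrame  # variant, position, wt_aa, alt_aa, alt_codon,
    # mut_class, true_abundance, true_activity, region_label, is_active_site
    active_site_positions: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class SortResult:
    """Cells per (replicate, bin, variant) with the gates used."""

    cell_counts: np.ndarray  # (n_replicates, 4, V) ints
    gates: np.ndarray  # (n_replicates, 3) bin boundaries
    variants: list[str]  # tokens, column order of cell_counts


def _region_labels(config: SimConfig) -> dict[int, str]:
    """Per-residue compartment labels: loops alternate starting cytoplasmic."""
    labels = {}
    segments = sorted(config.tmd_segments)
    side = "cytoplasmic"
    pos = 1
    for start, end in segments:
        for p in range(pos, start):
            labels[p] = side
        for p in range(start, end + 1):
            labels[p] = "TM"
        side = "lumenal" if side == "cytoplasmic" else "cytoplasmic"
        pos = end + 1
    for p in range(pos, config.protein_length + 1):
        labels[p] = side
    return labels


def simulate_reference(config: SimConfig, rng: np.random.Generator) -> ProteinReference:
    """Random stop-free coding sequence starting with ATG."""
    codons = ["ATG"]
    sense = sorted(standard_dna_table.forward_table)
    for _ in range(config.n_positions):
        codons.append(sense[rng.integers(len(sense))])
    return ProteinReference(
        name="synthetic",
        coding_sequence="".join(codons),
        mutagenized_range=config.mutagenized_range,
    )


def simulate_truth(config: SimConfig) -> TruthTable:
    rng = np.random.default_rng(config.seed)
    reference = simulate_reference(config, rng)
    labels = _region_labels(config)
    em = config.effect_model
    lo, hi = config.mutagenized_range
    positions = list(range(lo, hi + 1))

    tm_positions = {p for p in positions if labels[p] == "TM"}
    non_tm = [p for p in positions if p not in tm_positions]
    # active sites: non-TM so their abundance stays WT-like while activity drops
    pool = non_tm if len(non_tm) >= em.n_active_sites else positions
    active_sites = tuple(
        sorted(rng.choice(pool, size=em.n_active_sites, replace=False))
    )

    rows: list[dict] = []
    seen: set[str] = set()

    def add(variant: VariantKey, true_abundance: float, true_activity: float) -> None:
        if variant.token in seen:
            return
        seen.add(variant.token)
        rows.append(
            {
                "variant": variant.token,
                "position": variant.position,
                "wt_aa": variant.wt_aa,
                "alt_aa": variant.alt_aa,
                "alt_codon": variant.alt_codon,
                "mut_class": variant.mut_class.value,
                "true_abundance": true_abundance,
                "true_activity": true_activity,
                "region_label": labels[variant.position],
                "is_active_site": variant.position in active_sites,
            }
        )

    def missense_abundance(position: int, alt: str) -> float:
        in_tmd = position in tm_positions
        if in_tmd and (alt in CHARGED or alt == "P") and (
            rng.random() < em.charged_tmd_low_prob
        ):
            comp = 2
        else:
            comp = rng.choice(3, p=em.mixture_weights)
        return float(rng.normal(em.mixture_means[comp], em.mixture_sds[comp]))

    aliphatic = frozenset("GAVIL")
    for position in positions:
        wt = reference.wt_aa(position)
        alts = [a for a in AA20 if a != wt]
        k = config.n_missense_per_position
        if position in active_sites:
            k = max(k, 5)  # enough variants to satisfy the min-variant rule
        # stratified library design: guarantee one charged and one aliphatic
        # substitution per position so windowed class profiles are supported
        # everywhere, then fill the remainder at random
        chosen: list[str] = []
        for group in (CHARGED, aliphatic):
            pool_g = sorted(set(alts) & group)
            if pool_g and len(chosen) < k:
                chosen.append(pool_g[rng.integers(len(pool_g))])
        remaining = [a for a in alts if a not in chosen]
        n_extra = min(k - len(chosen), len(remaining))
        if n_extra > 0:
            chosen.extend(rng.choice(remaining, size=n_extra, replace=False))
        for alt in chosen:
            codon = _CODONS_BY_AA[alt][rng.integers(len(_CODONS_BY_AA[alt]))]
            abundance = missense_abundance(position, alt)
            if position in active_sites:
                abundance = float(rng.normal(1.0, em.mixture_sds[0]))
                activity = float(
                    rng.normal(em.active_site_activity_mean, em.active_site_activity_sd)
                )
            else:
                activity = abundance + float(rng.normal(0.0, em.activity_noise_sd))
            add(
                VariantKey(position, wt, alt, alt_codon=codon),
                abundance,
                activity,
            )

    syn_eligible = [p for p in positions if len(_CODONS_BY_AA[reference.wt_aa(p)]) > 1]
    for position in rng.choice(
        syn_eligible, size=min(config.n_synonymous, len(syn_eligible)), replace=False
    ):
        position = int(position)
        wt = reference.wt_aa(position)
        options = [c for c in _CODONS_BY_AA[wt] if c != reference.codon(position)]
        codon = options[rng.integers(len(options))]
        value = float(rng.normal(1.0, em.synonymous_sd))
        add(
            VariantKey(position, wt, wt, alt_codon=codon),
            value,
            value + float(rng.normal(0.0, em.activity_noise_sd)),
        )

    for position in rng.choice(
        positions, size=min(config.n_nonsense, len(positions)), replace=False
    ):
        position = int(position)
        wt = reference.wt_aa(position)
        codon = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        value = float(rng.normal(0.0, em.nonsense_sd))
        add(
            VariantKey(position, wt, STOP, alt_codon=codon),
            value,
            value + float(rng.normal(0.0, em.activity_noise_sd)),
        )

    frame = pd.DataFrame(rows).sort_values(["position", "variant"], kind="stable")
    frame = frame.reset_index(drop=True)
    return TruthTable(reference, frame, active_sites)


def simulate_sort(
    truth: TruthTable,
    config: SimConfig,
    value_column: str = "true_abundance",
) -> SortResult:
    """FACS quartile sort: Dirichlet library skew, per-cell Gaussian noise,
    gates at the pooled empirical quartiles of each replicate."""
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    if config.cells_sorted < len(truth):
        warnings.warn(
            "cells_sorted is below the number of variants; expect dropout",
            stacklevel=2,
        )
    stream = sum(ord(c) for c in value_column)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB1, stream]))
    values = truth.variants[value_column].to_numpy(float)
    n_var = len(values)

    counts = np.zeros((config.n_replicates, 4, n_var), dtype=np.int64)
    gates = np.zeros((config.n_replicates, 3))
    for rep in range(config.n_replicates):
        props = rng.dirichlet(
            np.full(n_var, config.library_skew_concentration)
        )
        cells = rng.multinomial(config.cells_sorted, props)
        variant_of_cell = np.repeat(np.arange(n_var), cells)
        fluor = values[variant_of_cell] + rng.normal(
            0.0, config.cell_noise_sd, size=variant_of_cell.size
        )
        q = np.quantile(fluor, [0.25, 0.5, 0.75])
        gates[rep] = q
        bin_of_cell = np.searchsorted(q, fluor, side="right")
        flat = np.bincount(variant_of_cell * 4 + bin_of_cell, minlength=n_var * 4)
        counts[rep] = flat.reshape(n_var, 4).T
    return SortResult(counts, gates, truth.variants["variant"].tolist())


def simulate_barcodes(truth: TruthTable, config: SimConfig) -> pd.DataFrame:
    """Assign each variant a shifted-Poisson number of unique random barcodes.

    Returns the barcode map in interchange format:
    columns barcode, variant, mut_class, n_reads, alt_codon.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBC]))
    bases = np.array(list("ACGT"))
    rows = []
    used: set[str] = set()
    mean_extra = max(config.n_barcodes_per_variant - 1.0, 0.0)
    for _, var in truth.variants.iterrows():
        k = 1 + rng.poisson(mean_extra)
        for _ in range(k):
            while True:
                barcode = "".join(
                    bases[rng.integers(0, 4, size=config.barcode_length)]
                )
                if barcode not in used:
                    used.add(barcode)
                    break
            rows.append(
                {
                    "barcode": barcode,
                    "variant": var["variant"],
                    "mut_class": var["mut_class"],
                    "n_reads": 1,
                    "alt_codon": var["alt_codon"],
                }
            )
    return pd.DataFrame(rows).sort_values("barcode", kind="stable").reset_index(
        drop=True
    )


def simulate_reads(
    sort_result: SortResult,
    barcode_map: pd.DataFrame,
    config: SimConfig,
    stream: int = 0,
) -> pd.DataFrame:
    """Multinomial sequencing of each bin: reads per barcode proportional to
    that barcode's share of cells in the bin.

    Returns a long table: replicate, bin, barcode, count. Every bin's counts
    sum exactly to ``reads_per_bin`` (when the bin holds any cells).
    ``stream`` decorrelates repeated sequencing runs of the same experiment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E0, stream]))
    variant_index = {v: i for i, v in enumerate(sort_result.variants)}
    mapped = barcode_map["variant"].map(variant_index)
    if mapped.isna().any():
        raise ValueError("barcode map references variants absent from the sort")
    bc_variant_idx = mapped.to_numpy(dtype=np.int64)
    barcodes = barcode_map["barcode"].to_numpy()
    n_bc_per_variant = np.bincount(
        bc_variant_idx, minlength=len(sort_result.variants)
    )
    if (n_bc_per_variant == 0).any():
        raise ValueError("every variant needs at least one barcode")

    rows = []
    n_reps = sort_result.cell_counts.shape[0]
    for rep in range(n_reps):
        for b in range(4):
            cells = sort_result.cell_counts[rep, b]  # per variant
            weights = cells[bc_variant_idx] / n_bc_per_variant[bc_variant_idx]
            total = weights.sum()
            if total == 0:
                continue
            reads = rng.multinomial(config.reads_per_bin, weights / total)
            nz = np.nonzero(reads)[0]
            for i in nz:
                rows.append((f"R{rep + 1}", b + 1, barcodes[i], int(reads[i])))
    return pd.DataFrame(rows, columns=["replicate", "bin", "barcode", "count"])


def write_fastq(
    read_counts: pd.DataFrame,
    out_dir: str | Path,
    config: SimConfig,
    quality: int = 37,
    error_rate: float = 0.0,
) -> list[Path]:
    """Emit one Phred+33 FASTQ per (replicate, bin) from a read-count table.

    ``error_rate`` is a per-base substitution probability applied to each
    emitted read (qualities untouched), for exercising downstream filters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA57]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qual_line = chr(33 + quality) * config.barcode_length
    bases = "ACGT"
    paths = []
    for (rep, b), group in read_counts.groupby(["replicate", "bin"], sort=True):
        path = out_dir / f"{rep}_bin{b}.fastq"
        with open(path, "w") as fh:
            serial = 0
            for barcode, count in zip(group["barcode"], group["count"]):
                for _ in range(count):
                    seq = barcode
                    if error_rate > 0:
                        chars = list(seq)
                        hits = np.nonzero(
                            rng.random(len(chars)) < error_rate
                        )[0]
                        for i in hits:
                            choices = bases.replace(chars[i], "")
                            chars[i] = choices[rng.integers(3)]
                        seq = "".join(chars)
                    serial += 1
                    fh.write(f"@{rep}_bin{b}_{serial}\n{seq}\n+\n{qual_line}\n")
        paths.append(path)
    return paths


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience: same configuration, different seed."""
    return replace(config, seed=seed)
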