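# sortscan

Analysis toolkit for binned-sort (sort-seq / VAMP-seq style) deep mutational
scanning experiments: from per-bin barcode sequencing counts to normalized
variant scores, confidence-interval classifications, membrane-topology
profiles, positional clustering, specific-activity active-site calling, and
coupling-based local secondary-structure annotation. A seeded generative
model of the whole experiment (library → FACS quartile sort → barcoded
sequencing) makes every stage testable without access to raw data.

## What it does

1. **Variant model / subassembly** (`sortscan.variant_model`) — collapse
   reads sharing a barcode into a consensus, call a single-codon variant
   against a coding reference, and build a filtered barcode → variant map
   (indels, multi-residue changes, ambiguous consensus and WT-identical
   sequences are rejected with explicit reasons).
2. **Synthetic sort-seq** (`sortscan.synthetic`) — generative model with a
   three-component effect mixture, charged/proline intolerance inside
   transmembrane segments, designated low-activity "active site" positions,
   Dirichlet library skew, per-cell Gaussian fluorescence noise, quartile
   gates per replicate, and multinomial per-bin sequencing (optionally as
   FASTQ).
3. **Barcode counting** (`sortscan.counting`) — per-(replicate, bin) variant
   count tables from FASTQ with a per-base Phred ≥ 20 filter on the barcode
   span, exact barcode matching, and merging into a replicate × bin × variant
   tensor.
4. **Scoring** (`sortscan.scoring`) — bin frequencies → representation
   filters (observed in ≥ 2 replicates, total frequency ≥ 1e-4) →
   bin-weighted averages (0.25/0.5/0.75/1) → min-max normalization anchored
   at the nonsense median (0) and synonymous median (1) → replicate mean,
   SD, SE and 95% CI.
5. **Classification** (`sortscan.classification`) — five-way calls
   (low / possibly low / possibly WT-like / WT-like / high) against the 5th
   and 95th percentiles of the synonymous score distribution, curated
   human-variant annotation, and a two-sided KS comparison of score
   distributions.
6. **Topology** (`sortscan.topology`) — width-10 centered sliding-window
   means of charged vs aliphatic substitution scores, contiguous low-region
   calling, and per-domain (cytoplasmic / TM / lumenal) score distributions.
7. **Position analysis** (`sortscan.positions`) — agglomerative clustering
   of per-position substitution-score vectors (pairwise-complete distances),
   dataset-wide [0, 1] rescaling, per-variant specific activity
   (rescaled activity / rescaled abundance), and constrained-position calling
   (lowest 12.5% of positional median specific activity with ≥ 4
   activity-scored variants).
8. **Couplings** (`sortscan.couplings`) — per-residue helix/strand scores
   from a residue-pair coupling matrix (helix: C(i,i+3)+C(i,i+4); strand:
   C(i,i+2)), segment calling (cores of ≥ 2 consecutive residues above
   1.5 / 0.75, extended by 1, minimum length 4), and hypergeometric overlap
   enrichment against a reference annotation.

## CLI

```bash
sortscan simulate --seed 1 --out-dir sim/            # synthetic experiment
sortscan count --fastq sim/R1_bin1.fastq --map sim/barcode_map.tsv \
    --replicate R1 --bin 1 --min-quality 20 --out counts.tsv
sortscan score --counts-dir sim/ --map sim/barcode_map.tsv --out scores.tsv
sortscan classify --scores scores.tsv --out classified.tsv
sortscan annotate-human --curated human.tsv --scores classified.tsv --out annotated.tsv
sortscan compare-ks --table classified.tsv --group-column mut_class \
    --group-a missense --group-b synonymous
sortscan topology --scores scores.tsv --length 163 --out profile.tsv
sortscan cluster --scores scores.tsv --k 4 --out groups.tsv
sortscan specific-activity --abundance abundance.tsv --activity activity.tsv \
    --out positions.tsv
sortscan couplings-ss --pairs couplings.tsv --out ss.tsv
```

All tables are plain TSV; FASTQ is Phred+33.

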