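# mutland

Mutation-landscape profiling of cancer cell-line panels.

`mutland` is for researchers who work with MAF-style somatic mutation
tables from large cell-line panels (CCLE-like hybrid-capture calls) and
want reproducible, auditable summary statistics rather than ad hoc
spreadsheet counts. It covers the full path from a raw mutation table to
publication-style numbers:

- **Filtering** — a fixed cascade removing intronic calls, synonymous
  (silent) calls, calls with allelic fraction below a floor (default
  10%), a configurable NOTCH4 exon-1 repeat-polymorphism window, followed
  by cell-type relabelling and a minimum-lines-per-type threshold
  (default 5). Every step is reported in an audit table.
- **Frequencies** — per-gene and per-gene-family mutation frequencies
  with the *one mutation per cell line* deduplication rule, optionally
  normalised to the family's average coding-sequence length (%/kbp).
  Mutation-type and per-receptor distributions count all mutations.
- **Domain mapping** — assignment of each positioned mutation to a
  protein domain from a gene-model config (EGF repeats, LNR, HD, TM,
  RAM, ANK, PEST; NRR = LNR ∪ HD), per-region fractions, a cysteine
  gain/loss scan (the CADASIL hallmark class), and a recurrent-position
  hotspot scan.
- **Impact & copy number** — classification of missense mutations as
  deleterious from externally computed subPSEC-style conservation scores
  (strictly below −3 on the [−10, 0] scale), and high-level
  amplification/deep-deletion frequencies from discrete GISTIC-style
  calls (±2 only).
- **Cohort comparison** — paired cell-line vs primary-tumor frequency
  differences per family and cell type, Δ% and length-normalised
  Δ%/10 kbp, ranked deterministically.
- **Synthetic cohorts** — a generator that emulates a ~900-line,
  20-cell-type panel with known ground truth (per-gene probabilities,
  injected decoys, hotspots), so every stage is testable offline.

## The statistics

For a gene family *F* (e.g. NOTCH1–4) and a stratum *S* of cell lines,

- frequency: `f(F, S) = 100 · |{lines in S with ≥1 mutation in any
  member of F}| / |S|` — each line counts at most once;
- length-normalised frequency: `f / (L̄(F)/1000)` in %/kbp, where `L̄(F)`
  is the arithmetic mean CDS length of the members;
- cohort delta: `Δ = f_cell_lines − f_tumors`, normalised to
  `Δ / (L̄(F)/10000)` in %/10 kbp;
- multi-mutation fraction: percentage of all lines with ≥2 mutation
  records across the family;
- deleterious call: subPSEC score `s` → deleterious iff `s < −3`
  (strict; `s = −3` is tolerated).

## Worked example

```python
from mutland import (GeneFamily, family_frequency, filter_records,
                     load_default_gene_models, multi_mutation_fraction,
                     normalize_by_length, relabel_and_threshold_cell_types)
from mutland.domains import hotspot_scan, region_fraction
from mutland.simulate import ccle_like_spec, generate_cohort

models = load_default_gene_models()
spec = ccle_like_spec(seed=7, gene_models=models)
records, annotations, truth = generate_cohort(spec)
records, report = filter_records(records)
records, annotations, _ = relabel_and_threshold_cell_types(records, annotations)

notch = GeneFamily("NOTCH", ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"))
entry = normalize_by_length(
    family_frequency(records, annotations, notch), notch, models, "per_kbp"
)
print(f"NOTCH1-4 mutated lines: {entry.n_mutated_lines}/{entry.n_lines} "
      f"({entry.frequency_pct:.1f}%, {entry.per_kbp_pct:.2f} %/kbp)")
print(f"multi-mutation fraction: "
      f"{multi_mutation_fraction(records, annotations, notch):.1f}%")
print(f"NOTCH1 EGF-region fraction: "
      f"{region_fraction(records, 'NOTCH1', ('EGF',), models):.1f}%")
top = hotspot_scan([r for r in records if r.gene_symbol.startswith('NOTCH')])[0]
print(f"top hotspot: {top.gene_symbol} aa {top.protein_position} "
      f"({top.classification}, n={top.n_records})")
```

prints

```
NOTCH1-4 mutated lines: 181/905 (20.0%, 2.85 %/kbp)
multi-mutation fraction: 4.5%
NOTCH1 EGF-region fraction: 52.2%
top hotspot: NOTCH3 aa 1802 (frameshift, n=8)
```

20.0% of the 905 simulated lines carry at least one Notch-receptor
mutation (2.85% per kilobase of average Notch coding sequence), 4.5% of
lines carry two or more, about half of the NOTCH1 mutations sit in the
EGF-repeat region, and the scan recovers the injected recurrent
frameshift at NOTCH3 residue 1802.

The same analysis runs from the shell:

```sh
mutland simulate --seed 7 -o data/ --with-tumors --with-cna
mutland run -c config.yaml     # all stages, TSV outputs + manifest
mutland frequencies -m data/mutations.tsv -a data/annotations.tsv \
    --family NOTCH=NOTCH1,NOTCH2,NOTCH3,NOTCH4 -o freqs.tsv
```

`mutland run` writes one TSV per analysis panel (filter report, overall
and per-cell-type frequencies, type and receptor distributions,
positional/lollipop table, region fractions, hotspots, impact, CNA
frequencies, raw and ranked cohort deltas) plus a `manifest.yaml` with
input/output checksums.

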