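# Methods

## Scope and model

`mutland` summarises protein-level somatic mutation calls from a
cell-line panel. The unit of input is an annotated mutation call (gene,
sample, variant class, HGVS-p short-form protein change, allelic
fraction); there is no genome-coordinate handling, VCF ingestion or
variant calling. Protein coordinates are 1-based and domain intervals
are closed on both ends, so a residue equal to a domain boundary belongs
to the domain.

Two counting conventions coexist deliberately:

1. **Frequencies count cell lines.** A gene-family frequency is the
   fraction of annotated lines in a stratum carrying ≥1 mutation in any
   family member; a line never counts twice. The denominator is all
   annotated lines in the stratum, mutated or not — the panel provides
   no per-line coverage mask, so "sequenced lines" and "annotated lines"
   are treated as the same set.
2. **Distributions count mutations.** Mutation-type shares (missense /
   nonsense / frameshift / in-frame indel) and per-receptor shares use
   every record without deduplication. Splice and unclassifiable records
   contribute to line-level frequencies (the line is mutated) but are
   excluded from the four-class type distribution, with their count
   reported.

Length normalisation divides a percentage by the family's mean coding
length in kbp (or 10 kbp for cohort deltas), making large and small
genes comparable under a uniform-target-size null.

## Filter cascade

Order is fixed and audited step by step: (1) intronic calls and
coding-class calls lacking a protein position; (2) silent (synonymous)
calls; (3) calls with an allelic fraction present and `< 0.10`
(subclonal/artefact floor; records without the field pass, since
compliant panels are pre-filtered); (4) NOTCH4 calls inside the exon-1
repeat-tract window (default residues 1–30), a germline repeat-length
polymorphism that otherwise masquerades as recurrent somatic indels;
(5) optionally splice calls (kept by default). Afterwards, cell-type
labels are rewritten (`haematopoietic_and_lymphoid_tissue → blood`,
`skin → melanoma` by default) and any cell type with fewer than 5
annotated lines is dropped — the threshold counts lines, not mutated
lines. The cascade is total (unknown classes pass through, logged) and
idempotent.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `allelic_fraction_floor` | 0.10 | minimum variant allele fraction (fraction of reads) |
| `min_lines` | 5 | minimum annotated lines per retained cell type |
| `notch4_window` | NOTCH4 aa 1–30 | repeat-polymorphism blacklist window |
| `subpsec_threshold` | −3.0 | deleterious iff score strictly below (scale [−10, 0]) |
| `hotspot_min_count` | 3 | minimum recurrence at one (gene, position, class) |
| GISTIC calls counted | ±2 only | "high-level" amplification / deep deletion |

All are surfaced in the YAML run config; the defaults are the values the
analyses in this package are calibrated to.

## Gene models

The shipped `gene_models.yaml` uses canonical UniProt protein lengths
with `cds_length_bp = 3·(protein_length+1)` and approximate canonical
domain boundaries chosen by the package authors; EGF repeats are
annotated per-repeat for NOTCH1 (36 repeats, needed for repeat-level
summaries) and as single spans for NOTCH2-4. No single transcript choice
is authoritative for "coding region size", so the config is data:
analyses requiring transcript-exact boundaries should supply their own
file, which is validated at load (sorted, non-overlapping, within
protein length). The NRR is resolved as the union of the LNR and HD
domains; "EGF" expands to all `EGF_*` repeats. Frameshift and nonsense
records are assigned to the domain containing their start position, as
in positional (lollipop) plots, even though they truncate everything
downstream.

## Impact scores and copy number

subPSEC-style conservation scores are consumed, never computed: they
enter via a scored-records TSV joined on (gene, sample, position) or any
callable scorer. The bundled `mock_scorer` is a deterministic hash of
the mutation key mapped into [−10, 0]; it carries no biological signal
and exists for plumbing tests and demos only. The deleterious boundary
is strict (−3.0 itself is tolerated). Copy-number summaries use the
discrete call set {−2, −1, 0, +1, +2}; only ±2 are counted as events,
and the denominator is the distinct samples in the table.

## Synthetic cohorts

The generator emulates the *shape* of a hybrid-capture panel: 905 lines
over 20 cell types (sizes fixed in `DEFAULT_CELL_TYPES`), per-gene
per-cell-type Bernoulli mutation indicators, a second mutation in a
mutated line with probability 0.17, a class mixture (missense 0.62,
frameshift 0.16, nonsense 0.10, in-frame indel 0.06, splice 0.06,
matching the observed predominance of missense then frameshift calls),
positions uniform over the protein except for configured hotspot mass
(default: a recurrent frameshift at NOTCH3 residue 1802 with weight
0.15), allelic fractions `0.1 + 0.9·Beta(2,2)`, and decoy records
(intronic, silent, low-AF, NOTCH4-window) appended after the true
records in deterministic counts so filter audits are exact. True
positions skip the NOTCH4 blacklist window for the same reason.

Default per-gene probabilities are back-derived from reported aggregate
cell-line frequencies under within-line independence across family
members: NOTCH1 0.073 directly; NOTCH2/3/4 ≈ 0.050 so that the joint
NOTCH1-4 frequency is 20.4%; Ras genes 0.097 each (26.4% jointly); ErbB
genes 0.060 each (21.8%); TP53 0.60; APC 0.155; PTCH1/2 0.054 each
(10.5%); ligands 0.029–0.040; house-keeping genes 0.005. Probabilities
are uniform across cell types by default (real panels are strongly
heterogeneous — endometrial and colorectal lines carry far more
mutations than pleural or biliary lines; per-(gene, cell-type) overrides
exist for that). Paired tumor cohorts reuse the process with every
probability reduced by a margin (default 0.03, floored at 0), with
per-cell-type overrides — a negative margin emulates a stratum where
primary tumors are more mutated than lines (the melanoma pattern).

What passing tests on these cohorts show: the counting, deduplication,
filtering, domain-assignment and delta arithmetic are correct, and
parameters injected at generation are recovered within binomial error.
What they do not show: anything about real mutational processes — there
is no positional clustering beyond explicit hotspots (so domain-level
enrichment such as NRR/PEST clustering is *not* emulated), no mutational
signatures or trinucleotide context, no correlation between genes within
a line, and no real allele-fraction spectrum.

## Numerical and design choices

- Frequencies are exact rational counts scaled by 100; output tables
  round to 1 decimal (frequencies) or 2–4 decimals (fractions, scores);
  internal values keep full precision. Closure identities
  (normalise-then-invert, shares summing to 1) hold to 1e−9.
- Hotspot and delta rankings break ties by name/position alphabetically
  so output order is deterministic; the manifest records SHA-256
  checksums of every input and output, and identical configs and inputs
  produce byte-identical outputs.
- Degenerate inputs: empty record lists yield zero-count reports and
  flagged-empty distributions, not errors; a gene absent from the CNA
  table yields a flagged zero-sample entry; unparseable protein changes
  degrade to an `unknown` kind rather than erroring, because real MAF
  exports contain nulls for non-coding calls.
- The Methods-level ambiguity about whether synonymous calls were kept
  is resolved by removing them: every downstream statistic in this
  package concerns protein-altering classes.
- Test problem sizes (cohorts of tens to hundreds of lines; 905-line
  panels where panel scale matters) were chosen as the smallest sizes at
  which binomial bounds are meaningful.

## Known limitations

- The deduplication rule means a family frequency is not the sum of
  member frequencies; comparisons against naively summed figures will
  disagree by the overlap.
- Length normalisation assumes mutation opportunity scales with CDS
  length only; it ignores sequence composition and selection.
- Domain fractions use all positioned mutations (not deduplicated
  lines); with recurrent positions the two conventions diverge.
- The cohort comparison reports effect sizes only; no significance
  testing is attempted, and tumor denominators are whatever the supplied
  tables contain.
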