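"""Mutation-frequency statistics over a filtered cohort.

Two counting rules coexist and must not be mixed up:

* gene/family *frequencies* count **cell lines**, at most once per line
  (a line with three NOTCH1 mutations and one NOTCH2 mutation is one
  mutated line for the NOTCH family);
* *distributions* (mutation-type shares per cell type, per-receptor
  shares) count **all mutations** without deduplication.

Denominators for frequencies are always the annotated cell lines in the
stratum — mutated or not — so strata must come from the sample annotation
table, never from the mutation table alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .records import (
    Classification,
    FrequencyEntry,
    GeneFamily,
    GeneModel,
    MutationRecord,
    SampleAnnotation,
    TYPE_DISTRIBUTION_CLASSES,
)

ALL_STRATA = "ALL"

NOTCH_RECEPTORS = ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4")


def _stratum_samples(
    annotations: Sequence[SampleAnnotation], stratum: str
) -> set[str]:
    if stratum == ALL_STRATA:
        return {a.sample_id for a in annotations}
    samples = {a.sample_id for a in annotations if a.cell_type == stratum}
    if not samples:
        known = sorted({a.cell_type for a in annotations})
        raise ValueError(f"unknown stratum {stratum!r}; known: {', '.join(known)}")
    return samples


def family_frequency(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
    family: GeneFamily,
    stratum: str = ALL_STRATA,
) -> FrequencyEntry:
    """Fraction of lines in the stratum with >= 1 mutation in any member.

    Each line counts at most once no matter how many mutations or members
    are hit.
    """
    samples = _stratum_samples(annotations, stratum)
    members = set(family.members)
    mutated = {
        r.sample_id
        for r in records
        if r.gene_symbol in members and r.sample_id in samples
    }
    return FrequencyEntry(
        unit=family.name,
        stratum=stratum,
        n_mutated_lines=len(mutated),
        n_lines=len(samples),
    )


def gene_frequency(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
    gene: str,
    stratum: str = ALL_STRATA,
) -> FrequencyEntry:
    """Single-gene frequency (a one-member family)."""
    return family_frequency(records, annotations, GeneFamily.single(gene), stratum)


def normalize_by_length(
    entry: FrequencyEntry,
    family: GeneFamily,
    gene_models: dict[str, GeneModel],
    scale: str = "per_kbp",
) -> FrequencyEntry:
    """Attach a length-normalised frequency: %/kbp or %/10 kbp of the
    family's average coding-sequence length."""
    divisors = {"per_kbp": 1000.0, "per_10kbp": 10000.0}
    if scale not in divisors:
        raise ValueError(f"scale must be per_kbp or per_10kbp, got {scale!r}")
    avg_len = family.avg_cds_length_bp(gene_models)
    if avg_len <= 0:
        raise ValueError(f"family {family.name}: non-positive average CDS length")
    return replace(
        entry,
        per_kbp_pct=entry.frequency_pct / (avg_len / divisors[scale]),
        length_scale=scale,
    )


@dataclass(frozen=True)
class TypeDistribution:
    """Shares of the four protein-altering classes among ALL mutations in a
    stratum (no per-line dedup); ``n_excluded`` counts records outside the
    four classes (splice/other), which are excluded from the denominator."""

    stratum: str
    shares: dict[Classification, float]
    n_total: int
    n_excluded: int

    @property
    def empty(self) -> bool:
        return self.n_total == 0


def type_distribution(
    records: Sequence[MutationRecord],
    stratum: str = ALL_STRATA,
    class_bins: Sequence[Classification] = TYPE_DISTRIBUTION_CLASSES,
) -> TypeDistribution:
    """Relative distribution of mutation types among all mutations in the
    stratum. Restrict ``records`` to the gene set of interest first."""
    pool = [r for r in records if stratum == ALL_STRATA or r.cell_type == stratum]
    binned = [r for r in pool if r.classification in class_bins]
    n = len(binned)
    shares = {
        c: (sum(1 for r in binned if r.classification is c) / n if n else 0.0)
        for c in class_bins
    }
    return TypeDistribution(
        stratum=stratum, shares=shares, n_total=n, n_excluded=len(pool) - n
    )


def receptor_distribution(
    records: Sequence[MutationRecord],
    stratum: str = ALL_STRATA,
    genes: Sequence[str] = NOTCH_RECEPTORS,
) -> dict[str, float]:
    """Share of all mutations per gene across ``genes`` in the stratum;
    sums to 1 when any such mutation exists, all-zero otherwise."""
    pool = [
        r
        for r in records
        if r.gene_symbol in genes
        and (stratum == ALL_STRATA or r.cell_type == stratum)
    ]
    n = len(pool)
    return {
        g: (sum(1 for r in pool if r.gene_symbol == g) / n if n else 0.0)
        for g in genes
    }


def multi_mutation_fraction(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
    family: GeneFamily,
    stratum: str = ALL_STRATA,
) -> float:
    """Percentage of all annotated lines carrying >= 2 mutations (total
    record count) across the family members."""
    samples = _stratum_samples(annotations, stratum)
    members = set(family.members)
    counts: dict[str, int] = {}
    for r in records:
        if r.gene_symbol in members and r.sample_id in samples:
            counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
    n_multi = sum(1 for c in counts.values() if c >= 2)
    return 100.0 * n_multi / len(samples) if samples else 0.0


def frequency_table(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
    families: Sequence[GeneFamily],
    gene_models: dict[str, GeneModel],
    by_cell_type: bool = False,
) -> pd.DataFrame:
    """Tabulate family frequencies (overall or per cell type) with %/kbp."""
    strata = (
        sorted({a.cell_type for a in annotations}) if by_cell_type else [ALL_STRATA]
    )
    rows = []
    for family in families:
        for stratum in strata:
            entry = family_frequency(records, annotations, family, stratum)
            entry = normalize_by_length(entry, family, gene_models, "per_kbp")
            rows.append(
                {
                    "unit": entry.unit,
                    "stratum": entry.stratum,
                    "n_mutated_lines": entry.n_mutated_lines,
                    "n_lines": entry.n_lines,
                    "frequency_pct": round(entry.frequency_pct, 1),
                    "per_kbp_pct": round(entry.per_kbp_pct, 3),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["unit", "stratum", "n_mutated_lines", "n_lines", "frequency_pct", "per_kbp_pct"],
    )


def type_distribution_table(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
) -> pd.DataFrame:
    rows = []
    for stratum in sorted({a.cell_type for a in annotations}):
        dist = type_distribution(records, stratum)
        row = {"stratum": stratum, "n_mutations": dist.n_total, "n_excluded": dist.n_excluded}
        row.update({c.value: round(s, 4) for c, s in dist.shares.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def receptor_distribution_table(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
    genes: Sequence[str] = NOTCH_RECEPTORS,
) -> pd.DataFrame:
    rows = []
    for stratum in sorted({a.cell_type for a in annotations}):
        shares = receptor_distribution(records, stratum, genes)
        row = {"stratum": stratum}
        row.update({g: round(s, 4) for g, s in shares.items()})
        rows.append(row)
    return pd.DataFrame(rows)
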