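"""Cell-line vs primary-tumor frequency comparison.

For every paired (cell type, tumor dataset) stratum and every gene
family, the difference in percentage of mutated samples (delta-%) is
computed as cell lines minus tumors and normalised to the family's
average coding-sequence length (delta-% per 10 kbp) so that large and
small genes are comparable. Both cohorts are counted with the identical
one-mutation-per-sample rule. A positive delta indicates excess mutation
frequency acquired or selected in vitro.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import FrequencyEntry, GeneFamily, GeneModel


@dataclass(frozen=True)
class CohortDelta:
    family: str
    cell_type: str
    freq_cell_lines_pct: float
    freq_tumors_pct: float
    delta_pct: float
    delta_per_10kbp: float


def pair_cohorts(
    cellline_freqs: Sequence[FrequencyEntry],
    tumor_freqs: Sequence[FrequencyEntry],
    pairing: dict[str, str],
) -> list[tuple[str, str, FrequencyEntry, FrequencyEntry]]:
    """Match per-(family, stratum) frequency entries across the two cohorts.

    ``pairing`` maps cell-line cell-type labels to tumor dataset labels.
    Entries in strata not covered by the pairing are reported (logged via
    the returned list being smaller); a pairing that references a missing
    stratum on either side is a hard error naming it.
    """
    cl = {(e.unit, e.stratum): e for e in cellline_freqs}
    tm = {(e.unit, e.stratum): e for e in tumor_freqs}
    cl_strata = {s for _, s in cl}
    tm_strata = {s for _, s in tm}
    families = sorted({u for u, _ in cl})

    pairs = []
    for cell_type, tumor_label in pairing.items():
        if cell_type not in cl_strata:
            raise ValueError(f"pairing references missing cell-line stratum {cell_type!r}")
        if tumor_label not in tm_strata:
            raise ValueError(f"pairing references missing tumor cohort {tumor_label!r}")
        for family in families:
            if (family, cell_type) in cl and (family, tumor_label) in tm:
                pairs.append(
                    (cell_type, family, cl[(family, cell_type)], tm[(family, tumor_label)])
                )
    return pairs


def compute_deltas(
    pairs: Sequence[tuple[str, str, FrequencyEntry, FrequencyEntry]],
    families: Sequence[GeneFamily],
    gene_models: dict[str, GeneModel],
) -> list[CohortDelta]:
    """Delta-% and length-normalised delta-%/10 kbp per (family, cell type).

    Negative deltas are allowed (tumors more frequently mutated than cell
    lines).
    """
    lengths = {f.name: f.avg_cds_length_bp(gene_models) for f in families}
    deltas = []
    for cell_type, family, cl_entry, tm_entry in pairs:
        if family not in lengths:
            raise ValueError(f"no average CDS length for family {family!r}")
        avg_len = lengths[family]
        if avg_len <= 0:
            raise ValueError(f"family {family!r}: non-positive average CDS length")
        delta = cl_entry.frequency_pct - tm_entry.frequency_pct
        deltas.append(
            CohortDelta(
                family=family,
                cell_type=cell_type,
                freq_cell_lines_pct=cl_entry.frequency_pct,
                freq_tumors_pct=tm_entry.frequency_pct,
                delta_pct=delta,
                delta_per_10kbp=delta / (avg_len / 10000.0),
            )
        )
    return deltas


def rank_deltas(deltas: Sequence[CohortDelta]) -> list[CohortDelta]:
    """Sort by normalised delta descending; ties broken by family then
    cell type alphabetically, so the ranking is deterministic."""
    return sorted(deltas, key=lambda d: (-d.delta_per_10kbp, d.family, d.cell_type))


def delta_table(deltas: Sequence[CohortDelta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": d.family,
                "cell_type": d.cell_type,
                "freq_cell_lines_pct": round(d.freq_cell_lines_pct, 2),
                "freq_tumors_pct": round(d.freq_tumors_pct, 2),
                "delta_pct": round(d.delta_pct, 2),
                "delta_per_10kbp": round(d.delta_per_10kbp, 3),
            }
            for d in deltas
        ],
        columns=[
            "family",
            "cell_type",
            "freq_cell_lines_pct",
            "freq_tumors_pct",
            "delta_pct",
            "delta_per_10kbp",
        ],
    )
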