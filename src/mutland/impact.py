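"""Functional-impact classification and discrete copy-number summaries.

Missense mutations are classified with substitution position-specific
evolutionary conservation (subPSEC-style) scores on the [-10, 0] scale,
where 0 is neutral and -10 maximally deleterious; a score strictly below
-3 marks a mutation as likely deleterious. The scores themselves come
from an external tool (e.g. PANTHER cSNP) via a scored-records file or
any callable scorer — this package does not recompute conservation.

Copy-number frequencies use discrete GISTIC-style calls: only high-level
events (+2 amplification, -2 deep deletion) are counted; single-copy
gains/losses (+/-1) are ignored.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .domains import INTERDOMAIN, UNASSIGNED, assign_domain
from .records import Classification, CNARecord, GeneModel, MutationRecord

SUBPSEC_THRESHOLD = -3.0


@dataclass(frozen=True)
class ImpactScore:
    record: MutationRecord
    subpsec: float
    deleterious: bool


def classify_impact(
    scored_records: Sequence[tuple[MutationRecord, float]],
    threshold: float = SUBPSEC_THRESHOLD,
) -> list[ImpactScore]:
    """Classify missense records as deleterious when subPSEC < threshold.

    The inequality is strict: a score exactly at the threshold is NOT
    deleterious. Non-missense records or scores outside [-10, 0] are hard
    errors.
    """
    out = []
    for record, score in scored_records:
        if record.classification is not Classification.MISSENSE:
            raise ValueError(
                f"impact scoring applies to missense records only, got "
                f"{record.classification} ({record.gene_symbol}/{record.sample_id})"
            )
        if not (-10.0 <= score <= 0.0):
            raise ValueError(
                f"subPSEC score must be in [-10, 0], got {score} "
                f"({record.gene_symbol}/{record.sample_id})"
            )
        out.append(ImpactScore(record=record, subpsec=score, deleterious=score < threshold))
    return out


def deleterious_fraction(impacts: Sequence[ImpactScore]) -> float:
    """Percentage of scored missense mutations classified deleterious."""
    if not impacts:
        return 0.0
    return 100.0 * sum(1 for i in impacts if i.deleterious) / len(impacts)


def deleterious_domain_summary(
    impacts: Sequence[ImpactScore],
    gene_models: dict[str, GeneModel],
) -> dict[str, dict[str, tuple[int, int]]]:
    """Per gene: domain -> (n_deleterious, n_scored), including zero-count
    domains for completeness (plus interdomain/unassigned buckets)."""
    summary: dict[str, dict[str, list[int]]] = {}
    for impact in impacts:
        r = impact.record
        model = gene_models.get(r.gene_symbol)
        if model is None:
            domain = UNASSIGNED
        elif r.protein_position is None:
            domain = UNASSIGNED
        else:
            domain = assign_domain(r.protein_position, model)
        gene_summary = summary.setdefault(r.gene_symbol, {})
        if not gene_summary and model is not None:
            for name in model.domain_names():
                gene_summary[name] = [0, 0]
            gene_summary[INTERDOMAIN] = [0, 0]
        cell = gene_summary.setdefault(domain, [0, 0])
        cell[1] += 1
        if impact.deleterious:
            cell[0] += 1
    return {
        gene: {d: (c[0], c[1]) for d, c in domains.items()}
        for gene, domains in summary.items()
    }


def mock_scorer(record: MutationRecord) -> float:
    """Deterministic, range-correct stand-in scorer for tests and demos.

    Hashes (gene, position, ref, alt) to a reproducible value in [-10, 0].
    It carries no biological signal and is clearly labelled as synthetic;
    real analyses must supply externally computed conservation scores.
    """
    key = f"{record.gene_symbol}|{record.protein_position}|{record.ref_aa}|{record.alt_aa}"
    digest = hashlib.sha256(key.encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    return -10.0 * u


def score_records(
    records: Sequence[MutationRecord],
    scorer: Callable[[MutationRecord], float] = mock_scorer,
) -> list[tuple[MutationRecord, float]]:
    """Attach scores to the missense subset of ``records`` via ``scorer``."""
    return [
        (r, scorer(r))
        for r in records
        if r.classification is Classification.MISSENSE
    ]


def impact_table(impacts: Sequence[ImpactScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": i.record.gene_symbol,
                "sample": i.record.sample_id,
                "protein_position": i.record.protein_position,
                "ref_aa": i.record.ref_aa,
                "alt_aa": i.record.alt_aa,
                "subpsec": round(i.subpsec, 4),
                "deleterious": i.deleterious,
            }
            for i in impacts
        ],
        columns=["gene", "sample", "protein_position", "ref_aa", "alt_aa", "subpsec", "deleterious"],
    )


@dataclass(frozen=True)
class CNAFrequency:
    gene_symbol: str
    n_samples: int
    amplified_pct: float
    deleted_pct: float
    missing: bool = False


def cna_frequencies(
    cna_records: Sequence[CNARecord],
    genes: Sequence[str],
    n_samples: Optional[int] = None,
) -> list[CNAFrequency]:
    """High-level amplification (+2) and deep-deletion (-2) percentages per
    gene. The denominator is the number of distinct samples in the table
    unless given explicitly. A gene absent from the table yields a flagged
    zero-sample entry, not an error."""
    samples = {r.sample_id for r in cna_records}
    denom = n_samples if n_samples is not None else len(samples)
    by_gene: dict[str, list[CNARecord]] = {}
    for r in cna_records:
        by_gene.setdefault(r.gene_symbol, []).append(r)
    out = []
    for gene in genes:
        recs = by_gene.get(gene)
        if not recs or denom == 0:
            out.append(CNAFrequency(gene, 0, 0.0, 0.0, missing=True))
            continue
        n_amp = len({r.sample_id for r in recs if r.gistic_call == 2})
        n_del = len({r.sample_id for r in recs if r.gistic_call == -2})
        out.append(
            CNAFrequency(
                gene_symbol=gene,
                n_samples=denom,
                amplified_pct=100.0 * n_amp / denom,
                deleted_pct=100.0 * n_del / denom,
            )
        )
    return out


def cna_table(freqs: Sequence[CNAFrequency]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": f.gene_symbol,
                "n_samples": f.n_samples,
                "amplified_pct": round(f.amplified_pct, 2),
                "deleted_pct": round(f.deleted_pct, 2),
                "missing": f.missing,
            }
            for f in freqs
        ],
        columns=["gene", "n_samples", "amplified_pct", "deleted_pct", "missing"],
    )
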