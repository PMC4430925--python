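"""Mapping mutations onto receptor protein domains.

Positions falling in no annotated domain are labelled ``interdomain``;
records without a position are ``unassigned``. Frameshift and nonsense
records are assigned by their start position even though they truncate
everything downstream — this matches positional (lollipop-style)
plotting. The NRR (negative regulatory region) is the union of the LNR
and HD domains; the EGF-repeat region is the union of all domains whose
name is ``EGF`` or starts with ``EGF_``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import Classification, GeneModel, MutationRecord

INTERDOMAIN = "interdomain"
UNASSIGNED = "unassigned"

#: named composite regions resolvable against any gene model
NRR_REGION = ("LNR", "HD")


def assign_domain(position: int, gene_model: GeneModel) -> str:
    """Name of the unique domain containing ``position``, else interdomain.

    Positions beyond the protein length are a hard error (model/data
    mismatch)."""
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if position > gene_model.protein_length_aa:
        raise ValueError(
            f"{gene_model.gene_symbol}: position {position} beyond protein "
            f"length {gene_model.protein_length_aa}"
        )
    for dom in gene_model.domains:
        if dom.contains(position):
            return dom.name
    return INTERDOMAIN


@dataclass(frozen=True)
class DomainHit:
    record: MutationRecord
    gene_symbol: str
    domain_name: str
    label: Optional[str] = None  # e.g. cysteine gain/loss


def assign_domains(
    records: Sequence[MutationRecord], gene_models: dict[str, GeneModel]
) -> list[DomainHit]:
    hits = []
    for r in records:
        model = gene_models.get(r.gene_symbol)
        if model is None or r.protein_position is None:
            name = UNASSIGNED
        else:
            name = assign_domain(r.protein_position, model)
        hits.append(DomainHit(record=r, gene_symbol=r.gene_symbol, domain_name=name))
    return hits


def expand_region(gene_model: GeneModel, region: Sequence[str]) -> set[str]:
    """Resolve region names to concrete domain names of this model.

    A region name matches a domain exactly, or as a prefix group
    (``EGF`` matches ``EGF_1``..``EGF_36``). ``interdomain`` is allowed as
    a pseudo-domain. Unknown names are a hard error.
    """
    available = set(gene_model.domain_names())
    out: set[str] = set()
    for name in region:
        if name == INTERDOMAIN:
            out.add(INTERDOMAIN)
            continue
        matches = {d for d in available if d == name or d.startswith(name + "_")}
        if not matches:
            raise ValueError(
                f"{gene_model.gene_symbol}: unknown region name {name!r} "
                f"(domains: {', '.join(sorted(available))})"
            )
        out |= matches
    return out


def region_fraction(
    records: Sequence[MutationRecord],
    gene: str,
    region: Sequence[str],
    gene_models: dict[str, GeneModel],
) -> float:
    """Percentage of this gene's positioned mutations that fall inside the
    region (a set of domain names; unpositioned records are excluded from
    the denominator)."""
    model = gene_models[gene]
    region_names = expand_region(model, region) if region else set()
    positioned = [
        r for r in records if r.gene_symbol == gene and r.protein_position is not None
    ]
    if not positioned:
        return 0.0
    n_in = sum(
        1
        for r in positioned
        if assign_domain(r.protein_position, model) in region_names
    )
    return 100.0 * n_in / len(positioned)


def cysteine_change_scan(
    records: Sequence[MutationRecord],
    gene: str,
    region: Sequence[str],
    gene_models: dict[str, GeneModel],
) -> list[DomainHit]:
    """Missense mutations inside the region that gain or lose a cysteine.

    Cysteine gain/loss in the EGF repeats is the hallmark mutation class of
    CADASIL-type NOTCH3 alleles, hence a dedicated scan.
    """
    model = gene_models[gene]
    region_names = expand_region(model, region)
    hits = []
    for r in records:
        if r.gene_symbol != gene or r.classification is not Classification.MISSENSE:
            continue
        if r.ref_aa is None or r.alt_aa is None or r.protein_position is None:
            continue
        domain = assign_domain(r.protein_position, model)
        if domain not in region_names:
            continue
        if r.ref_aa == "C":
            hits.append(DomainHit(r, gene, domain, label="loss"))
        elif r.alt_aa == "C":
            hits.append(DomainHit(r, gene, domain, label="gain"))
    return hits


@dataclass(frozen=True)
class Hotspot:
    gene_symbol: str
    protein_position: int
    classification: Optional[Classification]
    n_records: int


def hotspot_scan(
    records: Sequence[MutationRecord],
    min_count: int = 3,
    same_class: bool = True,
) -> list[Hotspot]:
    """Recurrent-position scan: groups positioned records by
    (gene, position[, classification]) and reports groups with
    ``n >= min_count``, sorted by count descending, then gene and position
    ascending (deterministic)."""
    groups: dict[tuple, int] = {}
    for r in records:
        if r.protein_position is None:
            continue
        key = (r.gene_symbol, r.protein_position, r.classification if same_class else None)
        groups[key] = groups.get(key, 0) + 1
    hotspots = [
        Hotspot(gene_symbol=g, protein_position=p, classification=c, n_records=n)
        for (g, p, c), n in groups.items()
        if n >= min_count
    ]
    hotspots.sort(key=lambda h: (-h.n_records, h.gene_symbol, h.protein_position))
    return hotspots


def positional_table(
    records: Sequence[MutationRecord], gene_models: dict[str, GeneModel]
) -> pd.DataFrame:
    """Per-mutation positional table (lollipop-plot input): gene, sample,
    position, classification, assigned domain."""
    rows = []
    for hit in assign_domains(records, gene_models):
        r = hit.record
        rows.append(
            {
                "gene": r.gene_symbol,
                "sample": r.sample_id,
                "cell_type": r.cell_type,
                "protein_position": r.protein_position,
                "classification": r.classification.value,
                "domain": hit.domain_name,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "sample", "cell_type", "protein_position", "classification", "domain"],
    )


def region_fraction_table(
    records: Sequence[MutationRecord],
    genes: Sequence[str],
    gene_models: dict[str, GeneModel],
) -> pd.DataFrame:
    """EGF / NRR / PEST fractions per gene (percent of positioned
    mutations)."""
    rows = []
    for gene in genes:
        model = gene_models[gene]
        available = set(model.domain_names())
        row = {"gene": gene}
        for label, region in (("EGF", ("EGF",)), ("NRR", NRR_REGION), ("PEST", ("PEST",))):
            usable = [n for n in region if expandable(model, n)]
            row[f"{label.lower()}_pct"] = (
                round(region_fraction(records, gene, usable, gene_models), 2)
                if usable
                else None
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "egf_pct", "nrr_pct", "pest_pct"])


def expandable(gene_model: GeneModel, name: str) -> bool:
    try:
        expand_region(gene_model, (name,))
        return True
    except ValueError:
        return False


def hotspot_table(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": h.gene_symbol,
                "protein_position": h.protein_position,
                "classification": h.classification.value if h.classification else "any",
                "n_records": h.n_records,
            }
            for h in hotspots
        ],
        columns=["gene", "protein_position", "classification", "n_records"],
    )
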