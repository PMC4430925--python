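"""Record- and cohort-level filter cascade applied before any frequency.

The cascade mirrors the pre-processing used for hybrid-capture cell-line
mutation calls: non-coding and synonymous calls are removed, calls with a
low allelic fraction (subclonal / likely artefactual) are dropped, and a
known germline repeat-length polymorphism in NOTCH4 exon 1 is blacklisted
by amino-acid window. Cell-type relabelling and the minimum-lines-per-type
threshold operate on samples, not on mutation records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .records import (
    Classification,
    CODING_CLASSES,
    MutationRecord,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

#: default blacklist window for the NOTCH4 exon-1 repeat polymorphism:
#: the N-terminal polyleucine/polyglutamine tract encoded by the (CTG)n run.
DEFAULT_NOTCH4_WINDOW = ("NOTCH4", 1, 30)

DEFAULT_RELABEL_MAP = {
    "haematopoietic_and_lymphoid_tissue": "blood",
    "skin": "melanoma",
}


@dataclass
class FilterConfig:
    """Tunable parameters of the record-level cascade."""

    allelic_fraction_floor: float = 0.10
    notch4_window: tuple[str, int, int] = DEFAULT_NOTCH4_WINDOW
    drop_splice: bool = False


@dataclass
class FilterReport:
    """Audit trail of the cascade: per-step in/out counts chain."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)
    samples_removed: list[tuple[str, int]] = field(default_factory=list)

    def add_step(self, name: str, records_in: int, records_out: int) -> None:
        if records_out > records_in:
            raise ValueError(f"step {name}: records_out > records_in")
        if self.steps and self.steps[-1][2] != records_in:
            raise ValueError(f"step {name}: count chain broken")
        self.steps.append((name, records_in, records_out))

    def removed(self, step_name: str) -> int:
        for name, rin, rout in self.steps:
            if name == step_name:
                return rin - rout
        raise KeyError(step_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"filter": name, "records_in": rin, "records_out": rout, "removed": rin - rout}
                for name, rin, rout in self.steps
            ],
            columns=["filter", "records_in", "records_out", "removed"],
        )

    def log(self) -> None:
        for name, rin, rout in self.steps:
            logger.info("filter %-22s %6d -> %6d (removed %d)", name, rin, rout, rin - rout)
        for cell_type, n in self.samples_removed:
            logger.info("dropped cell type %s (%d lines)", cell_type, n)


def filter_records(
    records: Sequence[MutationRecord],
    config: Optional[FilterConfig] = None,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the record-level cascade, in order:

    1. drop intronic calls and coding-class calls without a protein position;
    2. drop silent (synonymous) calls;
    3. drop calls with an allelic fraction present and below the floor;
    4. drop NOTCH4 calls inside the configured exon-1 repeat window;
    5. optionally drop splice-site calls (kept by default).

    Filters are total: unknown classifications pass through (logged).
    """
    cfg = config or FilterConfig()
    report = FilterReport()
    current = list(records)

    def step(name: str, keep) -> None:
        nonlocal current
        n_in = len(current)
        current = [r for r in current if keep(r)]
        report.add_step(name, n_in, len(current))

    step(
        "non_coding",
        lambda r: r.classification is not Classification.INTRONIC
        and not (r.classification in CODING_CLASSES and r.protein_position is None),
    )
    step("silent", lambda r: r.classification is not Classification.SILENT)
    step(
        "low_allelic_fraction",
        lambda r: r.allelic_fraction is None or r.allelic_fraction >= cfg.allelic_fraction_floor,
    )
    gene, lo, hi = cfg.notch4_window
    step(
        "notch4_repeat_window",
        lambda r: not (
            r.gene_symbol == gene
            and r.protein_position is not None
            and lo <= r.protein_position <= hi
        ),
    )
    if cfg.drop_splice:
        step("splice", lambda r: r.classification is not Classification.SPLICE)

    n_other = sum(1 for r in current if r.classification is Classification.OTHER)
    if n_other:
        logger.info("%d records with unknown/other classification passed through", n_other)
    return current, report


def relabel_and_threshold_cell_types(
    records: Sequence[MutationRecord],
    annotations: Sequence[SampleAnnotation],
    min_lines: int = 5,
    relabel_map: Optional[dict[str, str]] = None,
) -> tuple[list[MutationRecord], list[SampleAnnotation], FilterReport]:
    """Rewrite cell-type labels, then drop cell types with < min_lines lines.

    The threshold counts annotated samples (cell lines), not mutation
    records. Every record's sample must be annotated (hard error listing
    offenders otherwise).
    """
    relabel = DEFAULT_RELABEL_MAP if relabel_map is None else relabel_map
    ann_by_sample = {a.sample_id: a for a in annotations}

    orphans = sorted({r.sample_id for r in records} - ann_by_sample.keys())
    if orphans:
        raise ValueError(
            "records reference unannotated sample(s): " + ", ".join(orphans[:20])
        )

    new_annotations = [
        SampleAnnotation(
            sample_id=a.sample_id,
            cell_type=relabel.get(a.cell_type, a.cell_type),
            cohort=a.cohort,
        )
        for a in annotations
    ]
    type_counts: dict[str, int] = {}
    for a in new_annotations:
        type_counts[a.cell_type] = type_counts.get(a.cell_type, 0) + 1
    dropped_types = {t for t, n in type_counts.items() if n < min_lines}

    report = FilterReport(
        samples_removed=sorted((t, type_counts[t]) for t in dropped_types)
    )
    kept_annotations = [a for a in new_annotations if a.cell_type not in dropped_types]
    kept_samples = {a.sample_id for a in kept_annotations}
    sample_type = {a.sample_id: a.cell_type for a in kept_annotations}

    n_in = len(records)
    new_records = [
        MutationRecord(
            gene_symbol=r.gene_symbol,
            sample_id=r.sample_id,
            cell_type=sample_type[r.sample_id],
            classification=r.classification,
            protein_position=r.protein_position,
            ref_aa=r.ref_aa,
            alt_aa=r.alt_aa,
            allelic_fraction=r.allelic_fraction,
        )
        for r in records
        if r.sample_id in kept_samples
    ]
    report.add_step("cell_type_threshold", n_in, len(new_records))
    return new_records, kept_annotations, report
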