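"""Core record types for the mutation-landscape pipeline.

Conventions used throughout the package:

* Protein coordinates are 1-based; domain intervals are closed on both
  ends (HGVS convention), so residue ``start_aa`` and ``end_aa`` both
  belong to the domain.
* Variant classes are normalised to a small enum
  (:class:`Classification`); the mapping from MAF vocabulary lives in
  :mod:`mutland.io`.
* A gene family is any named, non-empty set of gene symbols; its average
  coding-sequence length (used for %/kbp normalisation) is always computed
  from the member gene models, never stored independently.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class Classification(str, enum.Enum):
    """Normalised variant classification."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SILENT = "silent"
    SPLICE = "splice"
    INTRONIC = "intronic"
    OTHER = "other"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: the four protein-altering classes shown in mutation-type distributions
TYPE_DISTRIBUTION_CLASSES = (
    Classification.MISSENSE,
    Classification.NONSENSE,
    Classification.FRAMESHIFT,
    Classification.INFRAME_INDEL,
)

#: classes for which a protein position is required to keep the record
CODING_CLASSES = frozenset(TYPE_DISTRIBUTION_CLASSES)


class Cohort(str, enum.Enum):
    CELL_LINE = "cell_line"
    PRIMARY_TUMOR = "primary_tumor"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call after parsing/normalisation."""

    gene_symbol: str
    sample_id: str
    cell_type: str
    classification: Classification
    protein_position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    allelic_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.protein_position is not None and self.protein_position < 1:
            raise ValueError(
                f"protein_position must be >= 1, got {self.protein_position}"
            )
        if self.allelic_fraction is not None and not (
            0.0 <= self.allelic_fraction <= 1.0
        ):
            raise ValueError(
                f"allelic_fraction must be in [0, 1], got {self.allelic_fraction}"
            )
        if self.classification is Classification.MISSENSE:
            if (
                self.protein_position is None
                or self.ref_aa is None
                or self.alt_aa is None
            ):
                raise ValueError(
                    "missense records require protein_position, ref_aa and alt_aa "
                    f"({self.gene_symbol} {self.sample_id})"
                )


@dataclass(frozen=True)
class SampleAnnotation:
    """Maps one sample to its cell type and cohort."""

    sample_id: str
    cell_type: str
    cohort: Cohort = Cohort.CELL_LINE

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.cell_type:
            raise ValueError(f"cell_type must be non-empty for {self.sample_id}")


@dataclass(frozen=True)
class ProteinDomain:
    """A named closed interval [start_aa, end_aa] on the protein."""

    name: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < self.start_aa:
            raise ValueError(
                f"invalid domain interval {self.name}: "
                f"[{self.start_aa}, {self.end_aa}]"
            )

    def contains(self, position: int) -> bool:
        return self.start_aa <= position <= self.end_aa


@dataclass(frozen=True)
class GeneModel:
    """Coding length, protein length and ordered domain layout of one gene."""

    gene_symbol: str
    cds_length_bp: int
    protein_length_aa: int
    domains: tuple[ProteinDomain, ...] = ()

    def __post_init__(self) -> None:
        if self.cds_length_bp < 3:
            raise ValueError(f"{self.gene_symbol}: cds_length_bp must be >= 3")
        if self.protein_length_aa < 1:
            raise ValueError(f"{self.gene_symbol}: protein_length_aa must be >= 1")
        object.__setattr__(
            self, "domains", tuple(sorted(self.domains, key=lambda d: d.start_aa))
        )
        prev: Optional[ProteinDomain] = None
        for dom in self.domains:
            if dom.end_aa > self.protein_length_aa:
                raise ValueError(
                    f"{self.gene_symbol}: domain {dom.name} ends at {dom.end_aa}, "
                    f"beyond protein length {self.protein_length_aa}"
                )
            if prev is not None and dom.start_aa <= prev.end_aa:
                raise ValueError(
                    f"{self.gene_symbol}: domains {prev.name} and {dom.name} overlap"
                )
            prev = dom

    def domain_names(self) -> list[str]:
        return [d.name for d in self.domains]


@dataclass(frozen=True)
class GeneFamily:
    """A named set of genes analysed as one unit (e.g. NOTCH1-4)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"family {self.name} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"family {self.name} has duplicate members")
        object.__setattr__(self, "members", tuple(self.members))

    def avg_cds_length_bp(self, gene_models: dict[str, GeneModel]) -> float:
        """Arithmetic mean of member CDS lengths (bp)."""
        missing = [g for g in self.members if g not in gene_models]
        if missing:
            raise KeyError(
                f"family {self.name}: no gene model for {', '.join(missing)}"
            )
        return statistics.fmean(
            gene_models[g].cds_length_bp for g in self.members
        )

    @classmethod
    def single(cls, gene_symbol: str) -> "GeneFamily":
        return cls(name=gene_symbol, members=(gene_symbol,))


GISTIC_CALLS = frozenset({-2, -1, 0, 1, 2})


@dataclass(frozen=True)
class CNARecord:
    """A discrete (GISTIC-style) copy-number call for one gene in one sample."""

    gene_symbol: str
    sample_id: str
    gistic_call: int

    def __post_init__(self) -> None:
        if self.gistic_call not in GISTIC_CALLS:
            raise ValueError(
                f"gistic_call must be in {{-2..2}}, got {self.gistic_call} "
                f"({self.gene_symbol}/{self.sample_id})"
            )


@dataclass(frozen=True)
class FrequencyEntry:
    """A mutation frequency for one unit (gene or family) in one stratum.

    ``frequency_pct`` is the percentage of cell lines in the stratum with at
    least one mutation in the unit; ``per_kbp_pct`` is that percentage
    divided by the unit's average coding length in the chosen scale, set by
    :func:`mutland.frequencies.normalize_by_length`.
    """

    unit: str
    stratum: str
    n_mutated_lines: int
    n_lines: int
    per_kbp_pct: Optional[float] = None
    length_scale: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_mutated_lines <= self.n_lines):
            raise ValueError(
                f"{self.unit}/{self.stratum}: need 0 <= n_mutated_lines "
                f"({self.n_mutated_lines}) <= n_lines ({self.n_lines})"
            )

    @property
    def frequency_pct(self) -> float:
        if self.n_lines == 0:
            return 0.0
        return 100.0 * self.n_mutated_lines / self.n_lines


def index_annotations(
    annotations: Sequence[SampleAnnotation],
) -> dict[str, SampleAnnotation]:
    """Index annotations by sample_id, rejecting duplicates within a cohort."""
    out: dict[str, SampleAnnotation] = {}
    for ann in annotations:
        if ann.sample_id in out and out[ann.sample_id].cohort == ann.cohort:
            raise ValueError(f"duplicate sample_id in cohort: {ann.sample_id}")
        out[ann.sample_id] = ann
    return out
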