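"""Synthetic CCLE-shaped cohorts with known ground truth.

The generator emulates the shape of a hybrid-capture cell-line mutation
table: ~900 lines spread over ~20 cell types, per-gene per-cell-type
probabilities that a line carries at least one mutation, a realistic
mixture of mutation classes, positional hotspots, allelic fractions, and
injectable decoy records (intronic, silent, low allelic fraction,
NOTCH4 exon-1 window) whose counts are recorded so filter audits can be
exact. It does not model mutational signatures, trinucleotide context or
real allele spectra — it exists so every pipeline stage can be tested
against known counts without any download.

Determinism: one ``numpy.random.Generator`` stream per cohort, seeded
from ``spec.seed``; identical seeds give byte-identical output files.
True records are generated first (line by line, gene by gene), decoys are
appended afterwards, so injected counts are auditable from the ground
truth alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .records import (
    AMINO_ACIDS,
    Classification,
    CNARecord,
    Cohort,
    GeneModel,
    MutationRecord,
    SampleAnnotation,
)

#: classes the generator can draw for true records
_POSITIONED_CLASSES = {
    Classification.MISSENSE,
    Classification.NONSENSE,
    Classification.FRAMESHIFT,
    Classification.INFRAME_INDEL,
    Classification.SILENT,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Fractions of decoy records to append, relative to the number of
    true records (rounded to the nearest integer)."""

    intronic_frac: float = 0.0
    silent_frac: float = 0.0
    low_af_frac: float = 0.0
    notch4_window_frac: float = 0.0


@dataclass(frozen=True)
class Hotspot:
    gene: str
    position: int
    classification: Classification
    weight: float  # probability a mutation in this gene lands on the hotspot


ProbKey = Union[str, tuple[str, str]]


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic cohort.

    ``mutation_prob`` keys are either a gene symbol (applies to every cell
    type) or a ``(gene, cell_type)`` pair (overrides the gene-wide value).
    """

    seed: int
    cell_types: Sequence[tuple[str, int]]
    gene_models: dict[str, GeneModel]
    mutation_prob: dict[ProbKey, float]
    extra_mutation_prob: float = 0.0
    class_mixture: dict[Classification, float] = field(
        default_factory=lambda: {
            Classification.MISSENSE: 0.62,
            Classification.FRAMESHIFT: 0.16,
            Classification.NONSENSE: 0.10,
            Classification.INFRAME_INDEL: 0.06,
            Classification.SPLICE: 0.06,
        }
    )
    hotspots: Sequence[Hotspot] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    tumor_margin: float = 0.0
    tumor_margin_overrides: dict[str, float] = field(default_factory=dict)
    af_floor: float = 0.10
    # true records avoid these per-gene windows so injected window-decoy
    # counts are exactly auditable in the filter report
    position_blacklist: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"NOTCH4": (1, 30)}
    )

    def validate(self) -> None:
        for key, p in self.mutation_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"mutation_prob[{key!r}] = {p} outside [0, 1]")
        if not (0.0 <= self.extra_mutation_prob <= 1.0):
            raise ValueError("extra_mutation_prob outside [0, 1]")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mixture weights sum to {total}, expected 1")
        for h in self.hotspots:
            model = self.gene_models.get(h.gene)
            if model is None:
                raise ValueError(f"hotspot gene {h.gene} has no gene model")
            if not (1 <= h.position <= model.protein_length_aa):
                raise ValueError(f"hotspot position {h.position} outside {h.gene}")
            if not (0.0 <= h.weight <= 1.0):
                raise ValueError("hotspot weight outside [0, 1]")
        for f in (
            self.noise.intronic_frac,
            self.noise.silent_frac,
            self.noise.low_af_frac,
            self.noise.notch4_window_frac,
        ):
            if f < 0:
                raise ValueError("noise fractions must be >= 0")

    def prob(self, gene: str, cell_type: str) -> float:
        if (gene, cell_type) in self.mutation_prob:
            return self.mutation_prob[(gene, cell_type)]
        return self.mutation_prob.get(gene, 0.0)


@dataclass
class GroundTruth:
    """Exact counts realised during generation."""

    n_lines: dict[str, int]
    mutated_lines: dict[str, dict[str, int]]  # gene -> cell_type -> count
    decoys: dict[str, int]
    hotspot_counts: dict[tuple[str, int, str], int]
    probabilities: dict[str, dict[str, float]]  # gene -> cell_type -> p

    def mutated_total(self, gene: str) -> int:
        return sum(self.mutated_lines.get(gene, {}).values())

    def to_dict(self) -> dict:
        return {
            "n_lines": dict(self.n_lines),
            "mutated_lines": {g: dict(cts) for g, cts in self.mutated_lines.items()},
            "decoys": dict(self.decoys),
            "hotspot_counts": {
                f"{g}:{p}:{c}": n for (g, p, c), n in self.hotspot_counts.items()
            },
        }


def _draw_aa(rng: np.random.Generator, exclude: Optional[str] = None) -> str:
    pool = AMINO_ACIDS if exclude is None else AMINO_ACIDS.replace(exclude, "")
    return pool[int(rng.integers(len(pool)))]


def _true_af(rng: np.random.Generator, floor: float) -> float:
    # clonal-ish allele fractions above the filter floor
    return round(float(floor + (1.0 - floor) * rng.beta(2.0, 2.0)), 4)


def _make_mutation(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    gene: str,
    sample_id: str,
    cell_type: str,
    hotspot_counts: dict[tuple[str, int, str], int],
) -> MutationRecord:
    model = spec.gene_models[gene]
    # hotspot mass first, then the class mixture with a uniform position
    for h in spec.hotspots:
        if h.gene == gene and rng.random() < h.weight:
            key = (h.gene, h.position, h.classification.value)
            hotspot_counts[key] = hotspot_counts.get(key, 0) + 1
            return _record_for_class(
                rng, spec, gene, sample_id, cell_type, h.classification, h.position
            )
    classes = list(spec.class_mixture.keys())
    weights = np.array([spec.class_mixture[c] for c in classes], dtype=float)
    cls = classes[int(rng.choice(len(classes), p=weights / weights.sum()))]
    position = (
        _draw_position(rng, spec, gene, model.protein_length_aa)
        if cls in _POSITIONED_CLASSES
        else None
    )
    return _record_for_class(rng, spec, gene, sample_id, cell_type, cls, position)


def _draw_position(
    rng: np.random.Generator, spec: GeneratorSpec, gene: str, length: int
) -> int:
    """Uniform position over [1, length], skipping the gene's blacklist
    window if one is configured."""
    window = spec.position_blacklist.get(gene)
    if window is None:
        return int(rng.integers(1, length + 1))
    lo, hi = window
    allowed = length - (hi - lo + 1)
    if allowed <= 0:
        raise ValueError(f"{gene}: blacklist window covers the whole protein")
    k = int(rng.integers(1, allowed + 1))
    return k + (hi - lo + 1) if k >= lo else k


def _record_for_class(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    gene: str,
    sample_id: str,
    cell_type: str,
    cls: Classification,
    position: Optional[int],
    allelic_fraction: Optional[float] = None,
) -> MutationRecord:
    ref = alt = None
    if position is not None:
        ref = _draw_aa(rng)
        if cls is Classification.MISSENSE:
            alt = _draw_aa(rng, exclude=ref)
        elif cls is Classification.NONSENSE:
            alt = "*"
        elif cls is Classification.SILENT:
            alt = ref
    af = (
        allelic_fraction
        if allelic_fraction is not None
        else _true_af(rng, spec.af_floor)
    )
    return MutationRecord(
        gene_symbol=gene,
        sample_id=sample_id,
        cell_type=cell_type,
        classification=cls,
        protein_position=position,
        ref_aa=ref,
        alt_aa=alt,
        allelic_fraction=af,
    )


def generate_cohort(
    spec: GeneratorSpec,
    cohort: Cohort = Cohort.CELL_LINE,
    margin: float = 0.0,
    margin_overrides: Optional[dict[str, float]] = None,
) -> tuple[list[MutationRecord], list[SampleAnnotation], GroundTruth]:
    """Generate one cohort (mutations, annotations, ground truth).

    ``margin`` is subtracted from every mutation probability (floored at
    0, capped at 1) — used for paired primary-tumor cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    overrides = margin_overrides or {}

    annotations: list[SampleAnnotation] = []
    records: list[MutationRecord] = []
    genes = sorted(spec.gene_models)
    mutated: dict[str, dict[str, int]] = {g: {} for g in genes}
    probabilities: dict[str, dict[str, float]] = {g: {} for g in genes}
    hotspot_counts: dict[tuple[str, int, str], int] = {}
    n_lines: dict[str, int] = {}

    prefix = "CL" if cohort is Cohort.CELL_LINE else "PT"
    for cell_type, n in spec.cell_types:
        n_lines[cell_type] = n
        ct_margin = overrides.get(cell_type, margin)
        for i in range(n):
            sample_id = f"{prefix}_{cell_type}_{i:04d}"
            annotations.append(
                SampleAnnotation(sample_id=sample_id, cell_type=cell_type, cohort=cohort)
            )
            for gene in genes:
                p = min(max(spec.prob(gene, cell_type) - ct_margin, 0.0), 1.0)
                probabilities[gene][cell_type] = p
                if rng.random() >= p:
                    continue
                mutated[gene][cell_type] = mutated[gene].get(cell_type, 0) + 1
                records.append(
                    _make_mutation(rng, spec, gene, sample_id, cell_type, hotspot_counts)
                )
                if spec.extra_mutation_prob and rng.random() < spec.extra_mutation_prob:
                    records.append(
                        _make_mutation(rng, spec, gene, sample_id, cell_type, hotspot_counts)
                    )

    decoys = _append_decoys(rng, spec, records, annotations)
    truth = GroundTruth(
        n_lines=n_lines,
        mutated_lines={g: cts for g, cts in mutated.items() if cts},
        decoys=decoys,
        hotspot_counts=hotspot_counts,
        probabilities=probabilities,
    )
    return records, annotations, truth


def _append_decoys(
    rng: np.random.Generator,
    spec: GeneratorSpec,
    records: list[MutationRecord],
    annotations: Sequence[SampleAnnotation],
) -> dict[str, int]:
    """Append decoy records the filter cascade must remove; counts are
    deterministic (rounded fractions of the true-record count)."""
    n_true = len(records)
    genes = sorted(spec.gene_models)
    counts = {
        "intronic": int(round(spec.noise.intronic_frac * n_true)),
        "silent": int(round(spec.noise.silent_frac * n_true)),
        "low_af": int(round(spec.noise.low_af_frac * n_true)),
        "notch4_window": int(
            round(spec.noise.notch4_window_frac * n_true)
            if "NOTCH4" in spec.gene_models
            else 0
        ),
    }
    if not annotations:
        return {k: 0 for k in counts}

    def random_line() -> SampleAnnotation:
        return annotations[int(rng.integers(len(annotations)))]

    def random_gene() -> str:
        return genes[int(rng.integers(len(genes)))]

    for _ in range(counts["intronic"]):
        ann = random_line()
        records.append(
            MutationRecord(
                gene_symbol=random_gene(),
                sample_id=ann.sample_id,
                cell_type=ann.cell_type,
                classification=Classification.INTRONIC,
                allelic_fraction=_true_af(rng, spec.af_floor),
            )
        )
    for _ in range(counts["silent"]):
        ann = random_line()
        gene = random_gene()
        model = spec.gene_models[gene]
        records.append(
            _record_for_class(
                rng,
                spec,
                gene,
                ann.sample_id,
                ann.cell_type,
                Classification.SILENT,
                int(rng.integers(1, model.protein_length_aa + 1)),
            )
        )
    for _ in range(counts["low_af"]):
        ann = random_line()
        gene = random_gene()
        model = spec.gene_models[gene]
        low = round(float(rng.uniform(0.01, spec.af_floor * 0.98)), 4)
        records.append(
            _record_for_class(
                rng,
                spec,
                gene,
                ann.sample_id,
                ann.cell_type,
                Classification.MISSENSE,
                int(rng.integers(1, model.protein_length_aa + 1)),
                allelic_fraction=low,
            )
        )
    for _ in range(counts["notch4_window"]):
        ann = random_line()
        window_hi = min(30, spec.gene_models["NOTCH4"].protein_length_aa)
        records.append(
            _record_for_class(
                rng,
                spec,
                "NOTCH4",
                ann.sample_id,
                ann.cell_type,
                Classification.MISSENSE,
                int(rng.integers(1, window_hi + 1)),
            )
        )
    return counts


def generate_paired_tumor_cohort(
    spec: GeneratorSpec,
) -> tuple[list[MutationRecord], list[SampleAnnotation], GroundTruth]:
    """Paired primary-tumor cohort: same generative process with every
    probability reduced by ``spec.tumor_margin`` (per-cell-type overrides
    allowed, e.g. a negative margin for a melanoma-like stratum)."""
    tumor_spec = replace_seed(spec, spec.seed + 1)
    return generate_cohort(
        tumor_spec,
        cohort=Cohort.PRIMARY_TUMOR,
        margin=spec.tumor_margin,
        margin_overrides=spec.tumor_margin_overrides,
    )


def replace_seed(spec: GeneratorSpec, seed: int) -> GeneratorSpec:
    return replace(spec, seed=seed)


def generate_cna_table(
    gene_models: dict[str, GeneModel],
    annotations: Sequence[SampleAnnotation],
    seed: int,
    amp_prob: float = 0.03,
    del_prob: float = 0.015,
    gain_prob: float = 0.10,
    loss_prob: float = 0.10,
) -> list[CNARecord]:
    """Discrete GISTIC-style calls per gene x sample with given rates of
    high-level amplification (+2), deep deletion (-2) and low-level
    gain/loss (+/-1); remaining mass is diploid (0)."""
    rng = np.random.default_rng(seed)
    calls = np.array([2, -2, 1, -1, 0])
    probs = np.array(
        [amp_prob, del_prob, gain_prob, loss_prob, 1 - amp_prob - del_prob - gain_prob - loss_prob]
    )
    if probs[-1] < 0:
        raise ValueError("CNA probabilities exceed 1")
    out = []
    for gene in sorted(gene_models):
        for ann in annotations:
            call = int(rng.choice(calls, p=probs))
            out.append(CNARecord(gene_symbol=gene, sample_id=ann.sample_id, gistic_call=call))
    return out


# ---------------------------------------------------------------------------
# Default study conditions: a CCLE-like panel.
#
# Per-gene probabilities are back-derived from reported aggregate cell-line
# frequencies under within-line independence across family members
# (NOTCH1 7.3%; NOTCH1-4 jointly 20.4%; H/K/N-Ras 26.4%; ErbB1-4 21.8%;
# p53 60.0%; APC 15.5%; Patched1-2 10.5%; ligands 2.9-7.3%). House-keeping
# genes get a low background rate. Cell-type sizes total 905 lines across
# 20 types, with the raw panel labels (haematopoietic_and_lymphoid_tissue,
# skin) that the pipeline relabels to blood/melanoma.
# ---------------------------------------------------------------------------

DEFAULT_CELL_TYPES: tuple[tuple[str, int], ...] = (
    ("haematopoietic_and_lymphoid_tissue", 160),
    ("lung", 130),
    ("skin", 60),
    ("central_nervous_system", 60),
    ("breast", 58),
    ("large_intestine", 55),
    ("ovary", 50),
    ("pancreas", 44),
    ("stomach", 38),
    ("kidney", 34),
    ("bone", 28),
    ("liver", 28),
    ("endometrium", 27),
    ("urinary_tract", 27),
    ("oesophagus", 26),
    ("upper_aerodigestive_tract", 32),
    ("soft_tissue", 20),
    ("pleura", 11),
    ("autonomic_ganglia", 9),
    ("prostate", 8),
)

DEFAULT_GENE_PROBS: dict[ProbKey, float] = {
    "NOTCH1": 0.073,
    "NOTCH2": 0.050,
    "NOTCH3": 0.050,
    "NOTCH4": 0.049,
    "JAG1": 0.040,
    "JAG2": 0.035,
    "DLL1": 0.030,
    "DLL4": 0.029,
    "TP53": 0.600,
    "HRAS": 0.097,
    "KRAS": 0.097,
    "NRAS": 0.097,
    "EGFR": 0.060,
    "ERBB2": 0.060,
    "ERBB3": 0.060,
    "ERBB4": 0.060,
    "APC": 0.155,
    "PTCH1": 0.054,
    "PTCH2": 0.054,
    "GAPDH": 0.005,
    "ACTB": 0.005,
    "TUBB": 0.005,
    "RPL13A": 0.005,
}


def ccle_like_spec(seed: int, gene_models: dict[str, GeneModel]) -> GeneratorSpec:
    """The default CCLE-like study conditions (905 lines, 20 cell types)."""
    models = {g: m for g, m in gene_models.items() if g in DEFAULT_GENE_PROBS}
    return GeneratorSpec(
        seed=seed,
        cell_types=DEFAULT_CELL_TYPES,
        gene_models=models,
        mutation_prob={g: p for g, p in DEFAULT_GENE_PROBS.items() if g in models},
        extra_mutation_prob=0.17,
        hotspots=(
            Hotspot("NOTCH3", 1802, Classification.FRAMESHIFT, 0.15),
        ),
        noise=NoiseSpec(
            intronic_frac=0.06,
            silent_frac=0.06,
            low_af_frac=0.03,
            notch4_window_frac=0.01,
        ),
        tumor_margin=0.03,
        tumor_margin_overrides={"skin": -0.02, "lung": 0.0},
    )
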