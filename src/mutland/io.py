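"""Readers and writers for the tabular inputs and outputs.

Two mutation-table dialects are supported:

``ccle_maf``
    MAF-style columns (``Hugo_Symbol``, ``Tumor_Sample_Barcode``,
    ``Variant_Classification``, ``Protein_Change``, optionally an allelic
    fraction column). The cell type is taken from the barcode suffix after
    the first underscore (``22RV1_PROSTATE`` → ``prostate``) unless a
    ``cell_type`` column is present.

``generic_tsv``
    The package's own plain dialect: ``gene``, ``sample``, ``cell_type``,
    ``classification``, ``protein_change``, ``allelic_fraction``. This is
    also the dialect the synthetic generator emits.

Unknown variant-classification strings degrade to ``other`` (with a
warning); rows missing a gene or sample are dropped and counted.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .records import (
    Classification,
    CNARecord,
    Cohort,
    GeneModel,
    MutationRecord,
    ProteinDomain,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# MAF Variant_Classification vocabulary -> normalised classes. Shipped as
# data so a config can override it (see load_classification_map).
DEFAULT_CLASSIFICATION_MAP: dict[str, Classification] = {
    "Missense_Mutation": Classification.MISSENSE,
    "Nonsense_Mutation": Classification.NONSENSE,
    "Nonstop_Mutation": Classification.OTHER,
    "Frame_Shift_Del": Classification.FRAMESHIFT,
    "Frame_Shift_Ins": Classification.FRAMESHIFT,
    "In_Frame_Del": Classification.INFRAME_INDEL,
    "In_Frame_Ins": Classification.INFRAME_INDEL,
    "Silent": Classification.SILENT,
    "Splice_Site": Classification.SPLICE,
    "Intron": Classification.INTRONIC,
    # generic dialect uses the enum values themselves
    **{c.value: c for c in Classification},
}


def load_classification_map(path: Optional[PathLike] = None) -> dict[str, Classification]:
    """Return the variant-classification mapping, optionally overridden from YAML."""
    mapping = dict(DEFAULT_CLASSIFICATION_MAP)
    if path is not None:
        with open(path) as fh:
            extra = yaml.safe_load(fh) or {}
        for key, value in extra.items():
            mapping[str(key)] = Classification(value)
    return mapping


_SUBST_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")
_FS_RE = re.compile(r"^p\.([A-Z*]?)(\d+)[A-Za-z*]*fs", re.IGNORECASE)
_INDEL_RE = re.compile(r"^p\.([A-Z]?)(\d+)(?:_[A-Z]?\d+)?(?:del|ins|dup)", re.IGNORECASE)
_POS_RE = re.compile(r"^p\.[A-Za-z*]*(\d+)")


def parse_protein_change(
    hgvsp: Optional[str],
) -> tuple[Optional[int], Optional[str], Optional[str], str]:
    """Parse an HGVS-p short-form protein change.

    Returns ``(protein_position, ref_aa, alt_aa, change_kind)`` where
    ``change_kind`` is one of ``substitution``, ``nonsense``, ``frameshift``,
    ``inframe_indel`` or ``unknown``. Total: never raises on malformed
    input; unparseable strings yield all-absent fields and ``unknown``.
    """
    if hgvsp is None:
        return None, None, None, "unknown"
    text = str(hgvsp).strip()
    if not text or text.lower() in {"nan", "na", ".", "p.?"}:
        return None, None, None, "unknown"

    m = _SUBST_RE.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "*":
            return pos, ref, "*", "nonsense"
        if alt == ref:
            return pos, ref, alt, "synonymous"
        return pos, ref, alt, "substitution"

    m = _FS_RE.match(text)
    if m:
        ref = m.group(1) or None
        return int(m.group(2)), ref, None, "frameshift"

    m = _INDEL_RE.match(text)
    if m:
        ref = m.group(1) or None
        return int(m.group(2)), ref, None, "inframe_indel"

    m = _POS_RE.match(text)
    if m:
        logger.warning("partially parseable protein change %r: kept position only", text)
        return int(m.group(1)), None, None, "unknown"

    logger.warning("unparseable protein change %r", text)
    return None, None, None, "unknown"


_CCLE_COLUMNS = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "classification": "Variant_Classification",
    "protein_change": "Protein_Change",
}
_GENERIC_COLUMNS = {
    "gene": "gene",
    "sample": "sample",
    "classification": "classification",
    "protein_change": "protein_change",
}


def _barcode_cell_type(barcode: str) -> str:
    """CCLE barcodes embed the tissue after the first underscore."""
    _, _, tissue = barcode.partition("_")
    return tissue.lower() if tissue else ""


def read_mutation_table(
    path: PathLike,
    dialect: str = "generic_tsv",
    classification_map: Optional[dict[str, Classification]] = None,
) -> list[MutationRecord]:
    """Read a tab-separated mutation table into :class:`MutationRecord` list.

    Raises ``ValueError`` if a mandatory column is missing or the file is
    empty; rows without a gene or sample are rejected with a logged count.
    """
    if dialect == "ccle_maf":
        cols = _CCLE_COLUMNS
    elif dialect == "generic_tsv":
        cols = _GENERIC_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    cmap = classification_map or DEFAULT_CLASSIFICATION_MAP

    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty mutation table: {path}") from None
    missing = [c for c in (cols["gene"], cols["sample"], cols["classification"]) if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    af_col = next(
        (c for c in ("allelic_fraction", "i_tumor_allelic_fraction", "tumor_f") if c in table.columns),
        None,
    )
    has_cell_type = "cell_type" in table.columns
    pchange_col = cols["protein_change"] if cols["protein_change"] in table.columns else None

    records: list[MutationRecord] = []
    n_rejected = 0
    unknown_classes: set[str] = set()
    for row in table.itertuples(index=False):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        gene = row_d.get(cols["gene"], "").strip()
        sample = row_d.get(cols["sample"], "").strip()
        if not gene or not sample:
            n_rejected += 1
            continue
        raw_class = row_d.get(cols["classification"], "").strip()
        classification = cmap.get(raw_class)
        if classification is None:
            unknown_classes.add(raw_class)
            classification = Classification.OTHER

        pos = ref = alt = None
        if pchange_col:
            pos, ref, alt, kind = parse_protein_change(row_d.get(pchange_col))
            if classification is Classification.MISSENSE and kind != "substitution":
                # keep the call but it cannot satisfy missense invariants
                logger.warning(
                    "missense row without parseable substitution (%s %s %r); demoted to other",
                    gene, sample, row_d.get(pchange_col),
                )
                classification = Classification.OTHER

        af = None
        if af_col:
            raw_af = row_d.get(af_col, "").strip()
            if raw_af:
                try:
                    af = float(raw_af)
                except ValueError:
                    logger.warning("non-numeric allelic fraction %r (%s %s)", raw_af, gene, sample)

        if has_cell_type:
            cell_type = row_d.get("cell_type", "").strip()
        elif dialect == "ccle_maf":
            cell_type = _barcode_cell_type(sample)
        else:
            cell_type = ""

        records.append(
            MutationRecord(
                gene_symbol=gene,
                sample_id=sample,
                cell_type=cell_type,
                classification=classification,
                protein_position=pos,
                ref_aa=ref,
                alt_aa=alt,
                allelic_fraction=af,
            )
        )

    if n_rejected:
        logger.warning("%s: rejected %d rows missing gene or sample", path, n_rejected)
    for cls in sorted(unknown_classes):
        logger.warning("%s: unmapped variant classification %r -> other", path, cls)
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: PathLike) -> None:
    """Write records in the generic TSV dialect (round-trips with the reader)."""
    rows = []
    for r in records:
        if r.classification is Classification.MISSENSE:
            pchange = f"p.{r.ref_aa}{r.protein_position}{r.alt_aa}"
        elif r.classification is Classification.NONSENSE and r.protein_position:
            pchange = f"p.{r.ref_aa or 'X'}{r.protein_position}*"
        elif r.classification is Classification.FRAMESHIFT and r.protein_position:
            pchange = f"p.{r.ref_aa or 'X'}{r.protein_position}fs"
        elif r.classification is Classification.INFRAME_INDEL and r.protein_position:
            pchange = f"p.{r.ref_aa or 'X'}{r.protein_position}del"
        elif r.classification is Classification.SILENT and r.protein_position:
            pchange = f"p.{r.ref_aa or 'X'}{r.protein_position}{r.ref_aa or 'X'}"
        elif r.protein_position:
            pchange = f"p.X{r.protein_position}"
        else:
            pchange = ""
        rows.append(
            {
                "gene": r.gene_symbol,
                "sample": r.sample_id,
                "cell_type": r.cell_type,
                "classification": r.classification.value,
                "protein_change": pchange,
                "allelic_fraction": "" if r.allelic_fraction is None else f"{r.allelic_fraction:.4f}",
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene", "sample", "cell_type", "classification", "protein_change", "allelic_fraction"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_annotations(path: PathLike) -> list[SampleAnnotation]:
    """Read a TSV with columns sample, cell_type and optional cohort."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample", "cell_type") if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    out = []
    for row in table.itertuples(index=False):
        cohort = Cohort(getattr(row, "cohort", "cell_line") or "cell_line")
        out.append(SampleAnnotation(sample_id=row.sample, cell_type=row.cell_type, cohort=cohort))
    return out


def write_sample_annotations(annotations: Iterable[SampleAnnotation], path: PathLike) -> None:
    pd.DataFrame(
        [
            {"sample": a.sample_id, "cell_type": a.cell_type, "cohort": a.cohort.value}
            for a in annotations
        ],
        columns=["sample", "cell_type", "cohort"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_models(path: PathLike) -> dict[str, GeneModel]:
    """Load the YAML gene-model config; all GeneModel invariants are
    validated at load (overlaps, out-of-range domains and duplicate genes
    are hard errors naming the offender)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or "genes" not in raw:
        raise ValueError(f"{path}: gene-model config must contain a 'genes' mapping")
    models: dict[str, GeneModel] = {}
    for gene, entry in raw["genes"].items():
        if gene in models:
            raise ValueError(f"{path}: duplicate gene {gene}")
        domains = tuple(
            ProteinDomain(name=d["name"], start_aa=int(d["start"]), end_aa=int(d["end"]))
            for d in entry.get("domains", []) or []
        )
        models[gene] = GeneModel(
            gene_symbol=gene,
            cds_length_bp=int(entry["cds_length_bp"]),
            protein_length_aa=int(entry["protein_length_aa"]),
            domains=domains,
        )
    return models


def default_gene_models_path() -> Path:
    return Path(__file__).parent / "data" / "gene_models.yaml"


def load_default_gene_models() -> dict[str, GeneModel]:
    """The shipped gene-model config (Notch receptors/ligands + comparators)."""
    return read_gene_models(default_gene_models_path())


def read_cna_table(path: PathLike) -> list[CNARecord]:
    """Read a discrete copy-number table.

    Accepts either a long form (columns gene, sample, gistic_call) or a
    gene x sample matrix with genes in the first column. Any cell outside
    {-2..2} or non-integer is a hard error naming row and column.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[CNARecord] = []
    lowered = [c.lower() for c in table.columns]
    if {"gene", "sample"}.issubset(lowered) and any(c in lowered for c in ("gistic_call", "call")):
        table.columns = lowered
        call_col = "gistic_call" if "gistic_call" in lowered else "call"
        for i, row in enumerate(table.itertuples(index=False)):
            records.append(_make_cna(getattr(row, "gene"), getattr(row, "sample"), getattr(row, call_col), i, call_col))
        return records
    # matrix form: first column = gene symbols, remaining columns = samples
    gene_col = table.columns[0]
    for i, row in table.iterrows():
        gene = row[gene_col]
        for sample in table.columns[1:]:
            records.append(_make_cna(gene, sample, row[sample], i, sample))
    return records


def _make_cna(gene: str, sample: str, raw: str, row_idx: int, col: str) -> CNARecord:
    try:
        value = int(str(raw).strip())
    except ValueError:
        raise ValueError(f"non-integer copy-number call {raw!r} at row {row_idx}, column {col!r}") from None
    try:
        return CNARecord(gene_symbol=gene, sample_id=sample, gistic_call=value)
    except ValueError as exc:
        raise ValueError(f"row {row_idx}, column {col!r}: {exc}") from None


def write_cna_table(records: Iterable[CNARecord], path: PathLike) -> None:
    pd.DataFrame(
        [{"gene": r.gene_symbol, "sample": r.sample_id, "gistic_call": r.gistic_call} for r in records],
        columns=["gene", "sample", "gistic_call"],
    ).to_csv(path, sep="\t", index=False)


def read_scored_records(path: PathLike) -> list[tuple[str, str, int, float]]:
    """Read a scored-records TSV: gene, sample, protein_position, subpsec."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "sample", "protein_position", "subpsec") if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return [
        (str(r.gene), str(r.sample), int(r.protein_position), float(r.subpsec))
        for r in table.itertuples(index=False)
    ]


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Convenience DataFrame view of a record list (analysis/debugging)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene_symbol,
                "sample": r.sample_id,
                "cell_type": r.cell_type,
                "classification": r.classification.value,
                "protein_position": r.protein_position,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "allelic_fraction": r.allelic_fraction,
            }
            for r in records
        ]
    )
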