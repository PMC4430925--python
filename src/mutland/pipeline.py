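"""End-to-end orchestration from a single YAML run config.

Stage order: filtering -> frequency analysis -> domain mapping ->
impact/CNA (if inputs given) -> cohort comparison (if a tumor cohort is
given). Every stage writes its TSV outputs into the output directory and
the run ends with a manifest (input checksums, config echo, versions,
filter report, skipped stages) so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from . import compare, domains, frequencies, impact as impact_mod, io as io_mod
from .filtering import (
    DEFAULT_NOTCH4_WINDOW,
    DEFAULT_RELABEL_MAP,
    FilterConfig,
    filter_records,
    relabel_and_threshold_cell_types,
)
from .records import Classification, GeneFamily, MutationRecord

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES: tuple[GeneFamily, ...] = (
    GeneFamily("NOTCH", ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4")),
    GeneFamily("NOTCH_LIGANDS", ("JAG1", "JAG2", "DLL1", "DLL4")),
    GeneFamily("RAS", ("HRAS", "KRAS", "NRAS")),
    GeneFamily("ERBB", ("EGFR", "ERBB2", "ERBB3", "ERBB4")),
    GeneFamily("TP53", ("TP53",)),
    GeneFamily("APC", ("APC",)),
    GeneFamily("PTCH", ("PTCH1", "PTCH2")),
)


@dataclass
class RunConfig:
    mutations: Path
    annotations: Path
    output_dir: Path
    gene_models: Optional[Path] = None
    dialect: str = "generic_tsv"
    cna: Optional[Path] = None
    scored_impact: Optional[Path] = None
    tumor_mutations: Optional[Path] = None
    tumor_annotations: Optional[Path] = None
    pairing: dict[str, str] = field(default_factory=dict)
    families: Sequence[GeneFamily] = DEFAULT_FAMILIES
    allelic_fraction_floor: float = 0.10
    min_lines: int = 5
    notch4_window: tuple[str, int, int] = DEFAULT_NOTCH4_WINDOW
    relabel_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RELABEL_MAP))
    drop_splice: bool = False
    subpsec_threshold: float = -3.0
    hotspot_min_count: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        families = tuple(
            GeneFamily(name, tuple(members))
            for name, members in (raw.pop("families", None) or {}).items()
        ) or DEFAULT_FAMILIES
        window = raw.pop("notch4_window", None)
        kwargs = {}
        for key in (
            "mutations", "annotations", "output_dir", "gene_models", "cna",
            "scored_impact", "tumor_mutations", "tumor_annotations",
        ):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw.pop(key))
            else:
                raw.pop(key, None)
        for key in (
            "dialect", "pairing", "allelic_fraction_floor", "min_lines",
            "relabel_map", "drop_splice", "subpsec_threshold",
            "hotspot_min_count", "seed",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValueError(f"unknown config keys: {', '.join(sorted(raw))}")
        cfg = cls(families=families, **kwargs)
        if window:
            cfg.notch4_window = (window[0], int(window[1]), int(window[2]))
        return cfg

    def validate(self) -> None:
        for label, path in (
            ("mutations", self.mutations),
            ("annotations", self.annotations),
            ("gene_models", self.gene_models),
            ("cna", self.cna),
            ("scored_impact", self.scored_impact),
            ("tumor_mutations", self.tumor_mutations),
            ("tumor_annotations", self.tumor_annotations),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write(df, out_dir: Path, name: str, manifest: dict) -> None:
    path = out_dir / name
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][name] = _sha256(path)


def match_scores(
    records: Sequence[MutationRecord],
    scored_rows: Sequence[tuple[str, str, int, float]],
) -> list[tuple[MutationRecord, float]]:
    """Join externally scored rows (gene, sample, position, subpsec) onto
    missense records; unmatched rows are logged and skipped."""
    index: dict[tuple[str, str, int], MutationRecord] = {}
    for r in records:
        if r.classification is Classification.MISSENSE and r.protein_position:
            index[(r.gene_symbol, r.sample_id, r.protein_position)] = r
    out = []
    n_unmatched = 0
    for gene, sample, position, score in scored_rows:
        record = index.get((gene, sample, position))
        if record is None:
            n_unmatched += 1
            continue
        out.append((record, score))
    if n_unmatched:
        logger.warning("%d scored rows had no matching missense record", n_unmatched)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "inputs": {},
        "outputs": {},
        "stages": {},
        "config": {
            "allelic_fraction_floor": config.allelic_fraction_floor,
            "min_lines": config.min_lines,
            "notch4_window": list(config.notch4_window),
            "subpsec_threshold": config.subpsec_threshold,
            "hotspot_min_count": config.hotspot_min_count,
            "families": {f.name: list(f.members) for f in config.families},
            "seed": config.seed,
        },
    }
    for label, path in (
        ("mutations", config.mutations),
        ("annotations", config.annotations),
        ("gene_models", config.gene_models),
        ("cna", config.cna),
        ("scored_impact", config.scored_impact),
        ("tumor_mutations", config.tumor_mutations),
        ("tumor_annotations", config.tumor_annotations),
    ):
        if path is not None:
            manifest["inputs"][label] = _sha256(Path(path))

    gene_models = (
        io_mod.read_gene_models(config.gene_models)
        if config.gene_models
        else io_mod.load_default_gene_models()
    )
    records = io_mod.read_mutation_table(config.mutations, dialect=config.dialect)
    annotations = io_mod.read_sample_annotations(config.annotations)

    # --- filtering ---------------------------------------------------
    fcfg = FilterConfig(
        allelic_fraction_floor=config.allelic_fraction_floor,
        notch4_window=config.notch4_window,
        drop_splice=config.drop_splice,
    )
    records, report = filter_records(records, fcfg)
    records, annotations, type_report = relabel_and_threshold_cell_types(
        records, annotations, min_lines=config.min_lines, relabel_map=config.relabel_map
    )
    report.steps.extend(type_report.steps)
    report.samples_removed.extend(type_report.samples_removed)
    report.log()
    _write(report.to_frame(), out_dir, "filter_report.tsv", manifest)
    manifest["stages"]["filtering"] = "ok"

    families = list(config.families)
    known_families = [
        f for f in families if all(g in gene_models for g in f.members)
    ]
    skipped_fams = sorted(set(f.name for f in families) - set(f.name for f in known_families))
    if skipped_fams:
        logger.warning("families without gene models skipped: %s", ", ".join(skipped_fams))

    # --- frequency analysis ------------------------------------------
    _write(
        frequencies.frequency_table(records, annotations, known_families, gene_models),
        out_dir, "frequencies_overall.tsv", manifest,
    )
    _write(
        frequencies.frequency_table(records, annotations, known_families, gene_models, by_cell_type=True),
        out_dir, "frequencies_by_celltype.tsv", manifest,
    )
    notch_records = [r for r in records if r.gene_symbol in frequencies.NOTCH_RECEPTORS]
    _write(
        frequencies.type_distribution_table(notch_records, annotations),
        out_dir, "type_distribution.tsv", manifest,
    )
    _write(
        frequencies.receptor_distribution_table(notch_records, annotations),
        out_dir, "receptor_distribution.tsv", manifest,
    )
    manifest["stages"]["frequency_analysis"] = "ok"

    # --- domain mapping ----------------------------------------------
    modeled = [r for r in records if r.gene_symbol in gene_models]
    _write(
        domains.positional_table(modeled, gene_models),
        out_dir, "positional_table.tsv", manifest,
    )
    notch_with_domains = [
        g for g in frequencies.NOTCH_RECEPTORS
        if g in gene_models and gene_models[g].domains
    ]
    _write(
        domains.region_fraction_table(records, notch_with_domains, gene_models),
        out_dir, "region_fractions.tsv", manifest,
    )
    hotspots = domains.hotspot_scan(modeled, min_count=config.hotspot_min_count)
    _write(domains.hotspot_table(hotspots), out_dir, "hotspots.tsv", manifest)
    manifest["stages"]["domain_mapping"] = "ok"

    # --- impact --------------------------------------------------------
    if config.scored_impact:
        scored = match_scores(records, io_mod.read_scored_records(config.scored_impact))
        impacts = impact_mod.classify_impact(scored, threshold=config.subpsec_threshold)
        _write(impact_mod.impact_table(impacts), out_dir, "impact_records.tsv", manifest)
        manifest["stages"]["impact"] = "ok"
        manifest["impact_deleterious_pct"] = round(
            impact_mod.deleterious_fraction(impacts), 2
        )
    else:
        manifest["stages"]["impact"] = "skipped"

    # --- CNA -----------------------------------------------------------
    if config.cna:
        cna_records = io_mod.read_cna_table(config.cna)
        freqs = impact_mod.cna_frequencies(cna_records, list(frequencies.NOTCH_RECEPTORS))
        _write(impact_mod.cna_table(freqs), out_dir, "cna_frequencies.tsv", manifest)
        manifest["stages"]["cna"] = "ok"
    else:
        manifest["stages"]["cna"] = "skipped"

    # --- cohort comparison ----------------------------------------------
    if config.tumor_mutations and config.tumor_annotations:
        t_records = io_mod.read_mutation_table(config.tumor_mutations, dialect=config.dialect)
        t_annotations = io_mod.read_sample_annotations(config.tumor_annotations)
        t_records, _ = filter_records(t_records, fcfg)
        t_records, t_annotations, _ = relabel_and_threshold_cell_types(
            t_records, t_annotations, min_lines=1, relabel_map=config.relabel_map
        )
        strata = sorted({a.cell_type for a in annotations})
        t_strata = sorted({a.cell_type for a in t_annotations})
        pairing = config.pairing or {s: s for s in strata if s in t_strata}

        cl_entries = [
            frequencies.family_frequency(records, annotations, fam, s)
            for fam in known_families
            for s in strata
        ]
        tm_entries = [
            frequencies.family_frequency(t_records, t_annotations, fam, s)
            for fam in known_families
            for s in t_strata
        ]
        pairs = compare.pair_cohorts(cl_entries, tm_entries, pairing)
        deltas = compare.compute_deltas(pairs, known_families, gene_models)
        _write(compare.delta_table(deltas), out_dir, "cohort_deltas.tsv", manifest)
        _write(
            compare.delta_table(compare.rank_deltas(deltas)),
            out_dir, "cohort_deltas_ranked.tsv", manifest,
        )
        manifest["stages"]["cohort_comparison"] = "ok"
    else:
        manifest["stages"]["cohort_comparison"] = "skipped"

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
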