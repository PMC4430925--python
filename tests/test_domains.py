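"""Domain assignment, region fractions, cysteine scan, hotspot scan."""

from collections import Counter

import pytest

from conftest import mk_record
from mutland.domains import (
    INTERDOMAIN,
    assign_domain,
    cysteine_change_scan,
    expand_region,
    hotspot_scan,
    region_fraction,
)
from mutland.records import Classification


def test_assign_domain_containment_and_interdomain(toy_model):
    assert assign_domain(10, toy_model) == "D1"
    assert assign_domain(30, toy_model) == "D1"  # closed interval boundary
    assert assign_domain(40, toy_model) == INTERDOMAIN
    assert assign_domain(100, toy_model) == INTERDOMAIN


def test_position_beyond_protein_is_hard_error(toy_model):
    with pytest.raises(ValueError, match="beyond protein"):
        assign_domain(101, toy_model)


def test_pest_position_maps_to_pest(gene_models):
    n1 = gene_models["NOTCH1"]
    pest = next(d for d in n1.domains if d.name == "PEST")
    assert assign_domain(pest.start_aa + 1, n1) == "PEST"


@pytest.mark.parametrize("gene", ["NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"])
def test_labels_partition_the_sequence(gene_models, gene):
    """Exhaustive sweep: every residue gets exactly one label and the
    per-domain label counts equal the interval widths."""
    model = gene_models[gene]
    counts = Counter(
        assign_domain(pos, model) for pos in range(1, model.protein_length_aa + 1)
    )
    for dom in model.domains:
        assert counts[dom.name] == dom.end_aa - dom.start_aa + 1
    assert sum(counts.values()) == model.protein_length_aa


class TestRegionFraction:
    def _records(self, gene_models):
        n1 = gene_models["NOTCH1"]
        egf = [d for d in n1.domains if d.name.startswith("EGF")]
        inside = [
            mk_record(gene="NOTCH1", sample=f"S{i}", position=egf[i].start_aa)
            for i in range(4)
        ]
        pest = next(d for d in n1.domains if d.name == "PEST")
        outside = [
            mk_record(gene="NOTCH1", sample=f"T{i}", position=pest.start_aa + i)
            for i in range(4)
        ]
        return inside + outside

    def test_hand_count(self, gene_models):
        records = self._records(gene_models)
        assert region_fraction(records, "NOTCH1", ("EGF",), gene_models) == pytest.approx(50.0)

    def test_empty_region_is_zero(self, gene_models):
        assert region_fraction(self._records(gene_models), "NOTCH1", (), gene_models) == 0.0

    def test_full_partition_sums_to_100(self, gene_models):
        records = self._records(gene_models)
        model = gene_models["NOTCH1"]
        full = tuple(model.domain_names()) + (INTERDOMAIN,)
        assert region_fraction(records, "NOTCH1", full, gene_models) == pytest.approx(100.0)

    def test_unknown_region_name_is_hard_error(self, gene_models):
        with pytest.raises(ValueError, match="KRINGLE"):
            region_fraction([], "NOTCH1", ("KRINGLE",), gene_models)

    def test_nrr_is_union_of_lnr_and_hd(self, gene_models):
        n1 = gene_models["NOTCH1"]
        lnr = next(d for d in n1.domains if d.name == "LNR")
        hd = next(d for d in n1.domains if d.name == "HD")
        records = [
            mk_record(gene="NOTCH1", sample="S1", position=lnr.start_aa),
            mk_record(gene="NOTCH1", sample="S2", position=hd.start_aa),
            mk_record(gene="NOTCH1", sample="S3", position=1),
            mk_record(gene="NOTCH1", sample="S4", position=1),
        ]
        assert region_fraction(records, "NOTCH1", ("LNR", "HD"), gene_models) == pytest.approx(50.0)

    def test_egf_prefix_expands_to_all_repeats(self, gene_models):
        n1 = gene_models["NOTCH1"]
        names = expand_region(n1, ("EGF",))
        assert len(names) == 36
        assert all(n.startswith("EGF_") for n in names)

    def test_unpositioned_records_excluded_from_denominator(self, gene_models):
        records = [
            mk_record(gene="NOTCH1", sample="S1", position=25),  # EGF_1
            mk_record(gene="NOTCH1", sample="S2", classification=Classification.SPLICE),
        ]
        assert region_fraction(records, "NOTCH1", ("EGF",), gene_models) == pytest.approx(100.0)


class TestCysteineScan:
    def test_loss_gain_and_neutral(self, gene_models):
        records = [
            mk_record(gene="NOTCH1", sample="S1", position=49, ref="C", alt="Y"),
            mk_record(gene="NOTCH1", sample="S2", position=90, ref="R", alt="C"),
            mk_record(gene="NOTCH1", sample="S3", position=123, ref="A", alt="T"),
        ]
        hits = cysteine_change_scan(records, "NOTCH1", ("EGF",), gene_models)
        assert [(h.record.sample_id, h.label) for h in hits] == [
            ("S1", "loss"),
            ("S2", "gain"),
        ]

    def test_non_missense_ignored(self, gene_models):
        records = [
            mk_record(
                gene="NOTCH1", sample="S1", position=49,
                classification=Classification.FRAMESHIFT, ref="C",
            )
        ]
        assert cysteine_change_scan(records, "NOTCH1", ("EGF",), gene_models) == []

    def test_outside_region_ignored(self, gene_models):
        n1 = gene_models["NOTCH1"]
        pest = next(d for d in n1.domains if d.name == "PEST")
        records = [mk_record(gene="NOTCH1", sample="S1", position=pest.start_aa, ref="C", alt="Y")]
        assert cysteine_change_scan(records, "NOTCH1", ("EGF",), gene_models) == []


class TestHotspotScan:
    def test_recurrent_frameshift_cluster(self):
        records = [
            mk_record(
                gene="NOTCH3", sample=f"S{i}", position=1802,
                classification=Classification.FRAMESHIFT,
            )
            for i in range(4)
        ] + [
            mk_record(gene="NOTCH3", sample="X1", position=100),
            mk_record(gene="NOTCH1", sample="X2", position=200),
        ]
        hotspots = hotspot_scan(records, min_count=3)
        assert len(hotspots) == 1
        h = hotspots[0]
        assert (h.gene_symbol, h.protein_position, h.n_records) == ("NOTCH3", 1802, 4)
        assert h.classification is Classification.FRAMESHIFT

    def test_all_singletons_gives_empty_list(self):
        records = [mk_record(sample=f"S{i}", position=i + 1) for i in range(5)]
        assert hotspot_scan(records) == []

    def test_min_count_one_equals_brute_force_grouping(self):
        records = [
            mk_record(gene=g, sample=f"S{i}", position=p, classification=c)
            for i, (g, p, c) in enumerate(
                [
                    ("NOTCH1", 5, Classification.MISSENSE),
                    ("NOTCH1", 5, Classification.MISSENSE),
                    ("NOTCH1", 5, Classification.NONSENSE),
                    ("NOTCH2", 7, Classification.MISSENSE),
                ]
            )
        ]
        oracle = Counter(
            (r.gene_symbol, r.protein_position, r.classification) for r in records
        )
        hotspots = hotspot_scan(records, min_count=1)
        got = {(h.gene_symbol, h.protein_position, h.classification): h.n_records for h in hotspots}
        assert got == dict(oracle)

    def test_same_class_false_pools_classes(self):
        records = [
            mk_record(gene="NOTCH1", sample="S1", position=5),
            mk_record(gene="NOTCH1", sample="S2", position=5, classification=Classification.NONSENSE),
        ]
        assert hotspot_scan(records, min_count=2, same_class=True) == []
        pooled = hotspot_scan(records, min_count=2, same_class=False)
        assert len(pooled) == 1 and pooled[0].n_records == 2

    def test_sorted_by_count_then_position(self):
        records = (
            [mk_record(gene="NOTCH1", sample=f"A{i}", position=50) for i in range(3)]
            + [mk_record(gene="NOTCH1", sample=f"B{i}", position=10) for i in range(5)]
            + [mk_record(gene="NOTCH1", sample=f"C{i}", position=20) for i in range(3)]
        )
        hotspots = hotspot_scan(records, min_count=3)
        assert [(h.protein_position, h.n_records) for h in hotspots] == [
            (10, 5),
            (20, 3),
            (50, 3),
        ]
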