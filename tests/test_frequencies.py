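"""Frequency statistics: dedup rule, length normalisation, distributions."""

import numpy as np
import pytest

from conftest import mk_annotations, mk_record
from mutland.frequencies import (
    family_frequency,
    gene_frequency,
    multi_mutation_fraction,
    normalize_by_length,
    receptor_distribution,
    type_distribution,
)
from mutland.records import Classification, GeneFamily, GeneModel


def brute_force_family_frequency(records, annotations, family, stratum="ALL"):
    """Independent oracle: per-line set membership, no shortcuts."""
    lines = [
        a.sample_id
        for a in annotations
        if stratum == "ALL" or a.cell_type == stratum
    ]
    n_mut = 0
    for line in lines:
        hit = False
        for r in records:
            if r.sample_id == line and r.gene_symbol in family.members:
                hit = True
        if hit:
            n_mut += 1
    return n_mut, len(lines)


def test_family_frequency_counts_each_line_once(notch_family):
    anns = mk_annotations(10)
    records = [
        mk_record(gene="NOTCH1", sample="S1"),
        mk_record(gene="NOTCH2", sample="S1", position=30),
        mk_record(gene="NOTCH3", sample="S2"),
    ]
    entry = family_frequency(records, anns, notch_family)
    assert (entry.n_mutated_lines, entry.n_lines) == (2, 10)
    assert entry.frequency_pct == 20.0


def test_family_frequency_bounds(notch_family):
    anns = mk_annotations(4)
    assert family_frequency([], anns, notch_family).frequency_pct == 0.0
    records = [mk_record(gene="NOTCH1", sample=f"S{i}") for i in range(1, 5)]
    assert family_frequency(records, anns, notch_family).frequency_pct == 100.0


def test_gene_frequency_dedups_within_gene():
    anns = mk_annotations(10)
    records = [
        mk_record(gene="NOTCH1", sample="S1", position=10),
        mk_record(gene="NOTCH1", sample="S1", position=20),
    ]
    assert gene_frequency(records, anns, "NOTCH1").frequency_pct == 10.0


def test_unknown_stratum_is_hard_error(notch_family):
    with pytest.raises(ValueError, match="unknown stratum"):
        family_frequency([], mk_annotations(3), notch_family, "kidney")


def test_family_frequency_matches_brute_force_on_random_cohorts(notch_family):
    """Dedup correctness against the set-membership oracle."""
    rng = np.random.default_rng(2024)
    genes = list(notch_family.members) + ["TP53"]
    for _ in range(120):
        n = int(rng.integers(2, 12))
        anns = mk_annotations(n)
        records = []
        for _ in range(int(rng.integers(0, 25))):
            records.append(
                mk_record(
                    gene=genes[int(rng.integers(len(genes)))],
                    sample=f"S{int(rng.integers(1, n + 1))}",
                    position=int(rng.integers(1, 200)),
                )
            )
        entry = family_frequency(records, anns, notch_family)
        n_mut, n_lines = brute_force_family_frequency(records, anns, notch_family)
        assert (entry.n_mutated_lines, entry.n_lines) == (n_mut, n_lines)
        # a member gene can never exceed its family
        gene_e = gene_frequency(records, anns, "NOTCH1")
        assert gene_e.frequency_pct <= entry.frequency_pct


def test_adding_a_record_never_decreases_frequency(notch_family):
    anns = mk_annotations(10)
    records = [mk_record(gene="NOTCH1", sample="S1")]
    before = family_frequency(records, anns, notch_family).frequency_pct
    for new_sample in ("S1", "S2"):
        after = family_frequency(
            records + [mk_record(gene="NOTCH4", sample=new_sample, position=99)],
            anns,
            notch_family,
        ).frequency_pct
        assert after >= before


class TestNormalization:
    MODELS = {"G8K": GeneModel("G8K", 8000, 2600)}
    FAM = GeneFamily("G8K", ("G8K",))

    def _entry(self):
        anns = mk_annotations(10)
        records = [mk_record(gene="G8K", sample=f"S{i}") for i in (1, 2)]
        return family_frequency(records, anns, self.FAM)

    def test_per_kbp(self):
        entry = normalize_by_length(self._entry(), self.FAM, self.MODELS, "per_kbp")
        assert entry.per_kbp_pct == pytest.approx(2.5)
        assert entry.frequency_pct == 20.0  # unchanged

    def test_per_10kbp(self):
        entry = normalize_by_length(self._entry(), self.FAM, self.MODELS, "per_10kbp")
        assert entry.per_kbp_pct == pytest.approx(25.0)

    def test_inverse_identity(self):
        entry = normalize_by_length(self._entry(), self.FAM, self.MODELS, "per_kbp")
        avg = self.FAM.avg_cds_length_bp(self.MODELS)
        assert entry.per_kbp_pct * (avg / 1000.0) == pytest.approx(
            entry.frequency_pct, abs=1e-9
        )

    def test_bad_scale_and_missing_model(self):
        with pytest.raises(ValueError, match="scale"):
            normalize_by_length(self._entry(), self.FAM, self.MODELS, "per_mbp")
        with pytest.raises(KeyError):
            normalize_by_length(
                self._entry(), GeneFamily("X", ("NOPE",)), self.MODELS
            )


class TestDistributions:
    def test_type_distribution_hand_count(self):
        records = (
            [mk_record(sample=f"S{i}", position=i + 1) for i in range(6)]
            + [
                mk_record(sample="S7", classification=Classification.NONSENSE),
                mk_record(sample="S8", classification=Classification.NONSENSE),
                mk_record(sample="S9", classification=Classification.FRAMESHIFT),
                mk_record(sample="S9", classification=Classification.FRAMESHIFT),
            ]
        )
        dist = type_distribution(records)
        assert dist.shares[Classification.MISSENSE] == pytest.approx(0.6)
        assert dist.shares[Classification.NONSENSE] == pytest.approx(0.2)
        assert dist.shares[Classification.FRAMESHIFT] == pytest.approx(0.2)
        assert dist.shares[Classification.INFRAME_INDEL] == 0.0
        assert dist.n_total == 10

    def test_single_mutation_share_is_one(self):
        dist = type_distribution([mk_record()])
        assert dist.shares[Classification.MISSENSE] == 1.0

    def test_splice_excluded_and_reported(self):
        records = [mk_record(), mk_record(sample="S2", classification=Classification.SPLICE)]
        dist = type_distribution(records)
        assert dist.n_total == 1 and dist.n_excluded == 1

    def test_empty_stratum_flagged_empty(self):
        dist = type_distribution([], "ALL")
        assert dist.empty and all(v == 0.0 for v in dist.shares.values())

    def test_receptor_distribution_two_receptor_stratum(self):
        records = [
            mk_record(gene="NOTCH1", sample="S1", cell_type="liver"),
            mk_record(gene="NOTCH1", sample="S2", cell_type="liver", position=44),
            mk_record(gene="NOTCH4", sample="S3", cell_type="liver", position=50),
            mk_record(gene="NOTCH4", sample="S4", cell_type="liver", position=60),
        ]
        shares = receptor_distribution(records, "liver")
        assert shares == {"NOTCH1": 0.5, "NOTCH2": 0.0, "NOTCH3": 0.0, "NOTCH4": 0.5}

    def test_shares_sum_to_one_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        genes = ["NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"]
        classes = [
            Classification.MISSENSE,
            Classification.NONSENSE,
            Classification.FRAMESHIFT,
            Classification.INFRAME_INDEL,
        ]
        for _ in range(60):
            records = [
                mk_record(
                    gene=genes[int(rng.integers(4))],
                    sample=f"S{int(rng.integers(1, 9))}",
                    classification=classes[int(rng.integers(4))],
                    position=int(rng.integers(1, 100)),
                )
                for _ in range(int(rng.integers(1, 30)))
            ]
            assert sum(type_distribution(records).shares.values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(receptor_distribution(records).values()) == pytest.approx(1.0, abs=1e-9)


class TestMultiMutationFraction:
    def test_hand_count(self, notch_family):
        anns = mk_annotations(10)
        records = [
            mk_record(gene="NOTCH1", sample="S1", position=10),
            mk_record(gene="NOTCH1", sample="S1", position=20),
            mk_record(gene="NOTCH1", sample="S2"),
            mk_record(gene="NOTCH3", sample="S2", position=30),
        ]
        assert multi_mutation_fraction(records, anns, notch_family) == pytest.approx(20.0)

    def test_no_multi_is_zero(self, notch_family):
        anns = mk_annotations(10)
        records = [mk_record(gene="NOTCH1", sample="S1")]
        assert multi_mutation_fraction(records, anns, notch_family) == 0.0

    def test_bounded_by_family_frequency(self, notch_family):
        rng = np.random.default_rng(5)
        for _ in range(40):
            anns = mk_annotations(8)
            records = [
                mk_record(
                    gene=f"NOTCH{int(rng.integers(1, 5))}",
                    sample=f"S{int(rng.integers(1, 9))}",
                    position=int(rng.integers(1, 100)),
                )
                for _ in range(int(rng.integers(0, 20)))
            ]
            multi = multi_mutation_fraction(records, anns, notch_family)
            fam = family_frequency(records, anns, notch_family).frequency_pct
            assert multi <= fam + 1e-12
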