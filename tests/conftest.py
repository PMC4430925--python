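import pytest
from hypothesis import HealthCheck, settings

from mutland.io import load_default_gene_models
from mutland.records import (
    Classification,
    GeneFamily,
    GeneModel,
    MutationRecord,
    ProteinDomain,
    SampleAnnotation,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gene_models():
    """The shipped default gene-model config."""
    return load_default_gene_models()


@pytest.fixture
def toy_model():
    """A 100-aa gene with two domains and an interdomain gap."""
    return GeneModel(
        gene_symbol="GENEA",
        cds_length_bp=303,
        protein_length_aa=100,
        domains=(
            ProteinDomain("D1", 10, 30),
            ProteinDomain("D2", 50, 80),
        ),
    )


def mk_record(
    gene="GENEA",
    sample="S1",
    cell_type="lung",
    classification=Classification.MISSENSE,
    position=15,
    ref="A",
    alt="T",
    af=0.4,
):
    """Terse MutationRecord factory for hand-built fixtures."""
    if classification is Classification.NONSENSE and alt == "T":
        alt = "*"
    if classification in (
        Classification.FRAMESHIFT,
        Classification.INFRAME_INDEL,
        Classification.SPLICE,
        Classification.INTRONIC,
        Classification.OTHER,
    ):
        alt = None
    if classification in (Classification.SPLICE, Classification.INTRONIC):
        position, ref = None, None
    return MutationRecord(
        gene_symbol=gene,
        sample_id=sample,
        cell_type=cell_type,
        classification=classification,
        protein_position=position,
        ref_aa=ref,
        alt_aa=alt,
        allelic_fraction=af,
    )


def mk_annotations(n, cell_type="lung", prefix="S", cohort=None):
    from mutland.records import Cohort

    return [
        SampleAnnotation(
            sample_id=f"{prefix}{i + 1}",
            cell_type=cell_type,
            cohort=cohort or Cohort.CELL_LINE,
        )
        for i in range(n)
    ]


@pytest.fixture
def notch_family():
    return GeneFamily("NOTCH", ("NOTCH1", "NOTCH2", "NOTCH3", "NOTCH4"))
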