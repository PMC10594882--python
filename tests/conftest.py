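import pytest

from cardiacg2p import fixtures, load_knowledge_base, vcfio
from cardiacg2p.consequence import AnnotatedVariant


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()


@pytest.fixture(scope="session")
def toy_transcripts():
    return fixtures.build_toy_transcripts()


@pytest.fixture(scope="session")
def grid_truth(tmp_path_factory):
    """The full combinatorial truth set, written to disk once per session."""
    spec = fixtures.make_grid_spec(seed=1)
    truth = fixtures.generate_truth_set(spec)
    paths = fixtures.write_truth_set(truth, tmp_path_factory.mktemp("grid"))
    return truth, paths


@pytest.fixture(scope="session")
def grid_selected(grid_truth, kb):
    truth, paths = grid_truth
    annotations = list(vcfio.read_annotated_vcf(paths["vcf"]))
    return vcfio.select_analysis_annotations(annotations, kb=kb)


def make_variant(**overrides) -> AnnotatedVariant:
    defaults = dict(
        chrom="chrT",
        pos=100,
        ref="A",
        alt="G",
        gene="MYH7",
        transcript_id="TX_MYH7",
        so_terms=frozenset({"missense_variant"}),
        population_af=1e-5,
    )
    defaults.update(overrides)
    if not isinstance(defaults["so_terms"], frozenset):
        defaults["so_terms"] = frozenset(defaults["so_terms"])
    return AnnotatedVariant(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant
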