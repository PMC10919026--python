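import pytest

from halomet import AnnotationTable, FeatureRecord, load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


def make_table(ec_lists, sample_id="S1", sample_kind="metagenome", size_bp=1_000_000):
    """Build an AnnotationTable from a list of per-feature EC collections."""
    features = [
        FeatureRecord(
            locus_tag=f"{sample_id}_{i:04d}",
            ftype="CDS",
            length_bp=900,
            ec_numbers=frozenset(ecs),
            product="synthetic gene",
        )
        for i, ecs in enumerate(ec_lists, start=1)
    ]
    return AnnotationTable(sample_id, sample_kind, size_bp, features)


@pytest.fixture()
def table_factory():
    return make_table
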