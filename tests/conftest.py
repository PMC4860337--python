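import pytest

from fetalis import compute_ic, load_canonical_panel
from fetalis.fixtures import mini_ontology, table1_cohort


@pytest.fixture(scope="session")
def ontology():
    onto, _ = mini_ontology()
    return onto


@pytest.fixture(scope="session")
def demo_panel():
    _, panel = mini_ontology()
    return panel


@pytest.fixture(scope="session")
def canonical_panel():
    return load_canonical_panel()


@pytest.fixture(scope="session")
def demo_icmap(ontology, demo_panel):
    return compute_ic(ontology, demo_panel)


@pytest.fixture(scope="session")
def canonical_icmap(ontology, canonical_panel):
    return compute_ic(ontology, canonical_panel)


@pytest.fixture(scope="session")
def cohort(canonical_panel, ontology):
    return table1_cohort(canonical_panel, ontology)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Materialized cohort input files, shared across the session."""
    from fetalis.fixtures import materialize_cohort

    out = tmp_path_factory.mktemp("cohort")
    manifest = materialize_cohort(out)
    return manifest
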