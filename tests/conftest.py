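import pytest
from hypothesis import settings

from narragraph.fixtures import FixtureConfig, generate_corpus, worked_example

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_bundle():
    return worked_example()


@pytest.fixture(scope="session")
def small_bundle():
    """A 20-document synthetic corpus with gold graphs and queries."""
    return generate_corpus(
        FixtureConfig(n_docs=20, seed=42, distractor_rate=0.3, n_queries=5)
    )


@pytest.fixture(scope="session")
def small_storage(small_bundle):
    """Gold-loaded storage + index for the small corpus."""
    storage = small_bundle.build_storage()
    index = storage.build_inverted_index()
    return storage, index


@pytest.fixture()
def toy_vocab_file(tmp_path):
    path = tmp_path / "vocab.tsv"
    path.write_text(
        "D019821\tDrug\tSimvastatin\tsimvastatin;synvinolin\n"
        "D006937\tDisease\tHypercholesterolemia\thypercholesterolemia\n"
        "DM\tDisease\tDiabetes Mellitus\tdiabetes mellitus;diabetes\n"
        "DM-1\tDisease\tDiabetes Mellitus Type 1\tdm type 1\n"
        "DM-2\tDisease\tDiabetes Mellitus Type 2\tdm type 2\n",
        encoding="utf-8",
    )
    return path


@pytest.fixture()
def toy_taxonomy_file(tmp_path):
    path = tmp_path / "taxonomy.tsv"
    path.write_text("DM\tDM-1\nDM\tDM-2\n", encoding="utf-8")
    return path
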