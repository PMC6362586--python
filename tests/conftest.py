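import numpy as np
import pytest

import tissuenet as tn


@pytest.fixture(scope="session")
def fixture_kb():
    kb, catalog, pathway = tn.worked_fixture()
    return kb


@pytest.fixture(scope="session")
def fixture_catalog():
    _, catalog, _ = tn.worked_fixture()
    return catalog


@pytest.fixture(scope="session")
def fixture_pathway():
    _, _, pathway = tn.worked_fixture()
    return pathway


@pytest.fixture(scope="session")
def fixture_combined(fixture_kb, fixture_pathway):
    return tn.induce_network(fixture_kb, fixture_pathway, "combined")


@pytest.fixture(scope="session")
def synthetic_kb():
    """Default-scale synthetic knowledge base (500 genes), shared per session."""
    return tn.generate_kb(tn.SyntheticConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def write_tsv(path, rows):
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n", encoding="utf-8")


INTERACTIONS_HEADER = ("source_id", "source_kind", "itype", "target_id", "target_kind", "directed")


@pytest.fixture()
def tiny_kb_file(tmp_path):
    """3-line knowledge graph: g1->p1 expression, p1-p2 interaction, g2->p2 expression."""
    path = tmp_path / "kb.tsv"
    write_tsv(
        path,
        [
            INTERACTIONS_HEADER,
            ("g1", "gene", "expression", "p1", "protein", "true"),
            ("p1", "protein", "interaction", "p2", "protein", "false"),
            ("g2", "gene", "expression", "p2", "protein", "true"),
        ],
    )
    return path
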