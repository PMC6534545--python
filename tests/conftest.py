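import pytest

from goscope import fixtures as fx
from goscope.ontology_io import propagate_annotations


@pytest.fixture(scope="session")
def worked():
    return fx.worked_fixtures()


@pytest.fixture(scope="session")
def random_dag_ann():
    """Factory: seeded random GO-like DAG plus propagated annotations."""

    def make(n_terms=20, n_genes=50, seed=0, n_roots=1, max_parents=3, rate=0.3):
        dag, direct = fx.random_godag(
            fx.FixtureSpec(
                n_terms=n_terms,
                n_genes=n_genes,
                n_roots=n_roots,
                max_parents=max_parents,
                direct_annotation_rate=rate,
                seed=seed,
            )
        )
        return dag, propagate_annotations(dag, direct)

    return make


def propagate(dag, direct):
    return propagate_annotations(dag, direct)
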