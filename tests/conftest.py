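import pytest
from hypothesis import HealthCheck, settings

from papnet import (
    GODag,
    OboTerm,
    SimulationConfig,
    propagate_annotations,
    simulate_study,
)
from papnet.io import AnnotationSet

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study():
    """One default synthetic study (66 proteins, published study design)."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def propagated(study):
    return propagate_annotations(study.dag, study.annotations)


@pytest.fixture()
def chain_dag():
    """root -> a -> b chain with annotation frequencies 1, 1/2, 1/4."""
    dag = GODag(
        [
            OboTerm("GO:0000001", "root", "biological_process"),
            OboTerm("GO:0000002", "a", "biological_process", ("GO:0000001",)),
            OboTerm("GO:0000003", "b", "biological_process", ("GO:0000002",)),
        ]
    )
    direct = frozenset(
        {
            ("g1", "GO:0000003"),
            ("g2", "GO:0000002"),
            ("g3", "GO:0000001"),
            ("g4", "GO:0000001"),
        }
    )
    return dag, AnnotationSet(direct=direct)
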