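import pytest

from cadhesion import (
    SyntheticSpec,
    generate_expression_table,
    load_packaged_kd_table,
    load_packaged_ontology,
)


@pytest.fixture(scope="session")
def graph():
    return load_packaged_ontology()


@pytest.fixture(scope="session")
def kd_table():
    return load_packaged_kd_table()


@pytest.fixture(scope="session")
def segment_ids(graph):
    return [s.id for s in graph.segments_at_level(3)]


@pytest.fixture(scope="session")
def p56_records(graph, segment_ids):
    """Synthetic P56 table over segments, plates, cortex units and nuclei."""
    plates = [s.id for s in graph.select(level=5)]
    units = [s.id for s in graph.cortical_units()]
    nuclei = [s.id for s in graph.subpallial_nuclei()]
    structures = segment_ids + plates + units + nuclei
    spec = SyntheticSpec(seed=11, n_structures=len(structures), ages=("P56",))
    return generate_expression_table(spec, structures=structures)
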