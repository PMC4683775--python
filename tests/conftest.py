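import pytest

from ose import fixtures


@pytest.fixture
def example():
    """The worked-example project, rebuilt per test."""
    return fixtures.build_example_project()


@pytest.fixture
def empty_model():
    from ose import bootstrap_task_ontology

    return bootstrap_task_ontology()


def by_name(model, name):
    """Look up a study element instance by its `name` slot."""
    inst = model.find_by_slot("_ELEMENT", "name", name)
    assert inst is not None, f"no instance named {name!r}"
    return inst
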