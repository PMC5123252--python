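import itertools
from random import Random

import pytest
from hypothesis import settings

from orthosandwich import ConstraintGraph, fixture_worked_example, fixture_coloring_example

settings.register_profile("suite", max_examples=30, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def worked_graph() -> ConstraintGraph:
    return fixture_worked_example()


@pytest.fixture
def coloring_example():
    return fixture_coloring_example()


def random_constraint_graph(rng: Random, n: int, n_species: int,
                            p_mandatory: float = 0.3, p_unknown: float = 0.25,
                            max_unknown: int | None = None) -> ConstraintGraph:
    """A random constraint graph over n genes and up to n_species species."""
    genes = [f"g{j}" for j in range(n)]
    assignment = {g: f"P{rng.randrange(n_species)}" for g in genes}
    mandatory, unknown = [], []
    for x, y in itertools.combinations(genes, 2):
        if assignment[x] == assignment[y]:
            continue
        r = rng.random()
        if r < p_mandatory:
            mandatory.append((x, y))
        elif r < p_mandatory + p_unknown:
            unknown.append((x, y))
    if max_unknown is not None and len(unknown) > max_unknown:
        unknown = unknown[:max_unknown]
    return ConstraintGraph.create(genes, mandatory, unknown, assignment)
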