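import numpy as np
import pytest

from mvh.grammar import (
    Grammar,
    Node,
    ObjectRepresentation,
    RuleProbabilities,
    assign_random_coords,
    sample_derivation,
)


@pytest.fixture(scope="session")
def grammar() -> Grammar:
    return Grammar()


@pytest.fixture(scope="session")
def uniform_rho(grammar) -> RuleProbabilities:
    return RuleProbabilities.uniform(grammar)


@pytest.fixture(scope="session")
def tiny_grammar() -> Grammar:
    """Two parts, two voxels: small enough for exhaustive oracles."""
    return Grammar(terminals=("P0", "P1"), voxels=((0, 0, 1), (0, 1, 0)))


def one_part_tree(part: str = "P0") -> ObjectRepresentation:
    return ObjectRepresentation(Node("S", [Node("P", [Node(part)])]))


def fig_layout_tree() -> ObjectRepresentation:
    """The worked five-part example: root S -> P S S S with parts
    P0, P1, P3, P5 and P7 nested one level deeper."""
    from mvh.stimuli import make_object

    return make_object(0)


def random_representation(grammar, seed, max_parts=8) -> ObjectRepresentation:
    rng = np.random.default_rng(seed)
    rho = RuleProbabilities.uniform(grammar)
    root = sample_derivation(grammar, rho, rng, max_parts=max_parts)
    assign_random_coords(root, grammar, rng)
    return ObjectRepresentation(root)


@pytest.fixture(scope="session")
def stimuli():
    from mvh.stimuli import all_objects

    return all_objects()
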