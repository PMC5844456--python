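"""Shared fixtures and independent oracles for the test suite."""

from collections import Counter

import numpy as np
import pytest

import chemotrace as ct
from chemotrace.phylogeny import BoundCharacters
from chemotrace.sankoff import ABSENT, MISSING, PRESENT


@pytest.fixture(scope="session")
def library():
    return ct.load_compound_library()


@pytest.fixture(scope="session")
def all_tables():
    """All three packaged detection tables, concatenated."""
    return ct.load_packaged_tables()


@pytest.fixture(scope="session")
def palpatores_tables():
    return ct.load_packaged_tables(("eupnoi", "dyspnoi"))


@pytest.fixture(scope="session")
def characters(all_tables):
    return ct.binarize(all_tables)


@pytest.fixture(scope="session")
def composite_tree():
    return ct.load_composite_tree()


@pytest.fixture(scope="session")
def bound(composite_tree, characters):
    return ct.bind(composite_tree, characters)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170139)


def bind_states(tree, states, character="trait"):
    """Bind a raw leaf->state mapping to a tree without a CharacterMatrix."""
    return BoundCharacters(tree, {character: dict(states)})


def random_binary_instance(rng, n_min=3, n_max=10, polytomy=0.4, missing=0.0):
    """A random tree plus random leaf states for oracle cross-checks."""
    n = int(rng.integers(n_min, n_max))
    tree = ct.random_tree(n, float(rng.uniform(0, polytomy)), rng)
    alphabet = [ABSENT, PRESENT] + ([MISSING] if missing else [])
    probs = None
    if missing:
        probs = [(1 - missing) / 2, (1 - missing) / 2, missing]
    states = {
        leaf.label: alphabet[int(rng.choice(len(alphabet), p=probs))]
        for leaf in tree.leaves()
    }
    return tree, states


def hartigan_length(tree, states):
    """Independent unit-cost parsimony length (Hartigan's algorithm).

    Exact for symmetric unit costs on rooted trees with polytomies; used to
    cross-check the Sankoff engine on a path it does not share.
    """
    changes = 0

    def walk(node):
        nonlocal changes
        if node.is_leaf:
            s = states[node.label]
            return {ABSENT, PRESENT} if s == MISSING else {s}
        child_sets = [walk(c) for c in node.children]
        counts = Counter(x for cs in child_sets for x in cs)
        top = max(counts.values())
        changes += len(child_sets) - top
        return {x for x, v in counts.items() if v == top}

    walk(tree.root)
    return changes
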