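import itertools

import numpy as np
import pytest

from bsptools.blocks import load_block_definitions
from bsptools.synth import default_panel_spec, generate_panel, prototype_core


def additive_matrix_from_random_tree(n_taxa, rng):
    """Random binary tree -> exact path-length (additive) distance matrix
    plus the tree's non-trivial bipartitions (leaf names ``t<i>``).

    Built by sequential joining, independent of the NJ implementation the
    tests exercise.
    """
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_taxa)}
    nxt = n_taxa
    active = list(range(n_taxa))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = nxt
        nxt += 1
        adj[parent] = []
        for child in (a, b):
            length = float(rng.uniform(0.05, 1.0))
            adj[parent].append((child, length))
            adj[child].append((parent, length))
        active = [x for x in active if x not in (a, b)] + [parent]

    def path_length(a, b):
        stack = [(a, 0.0, -1)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nb, ln in adj[node]:
                if nb != prev:
                    stack.append((nb, dist + ln, node))
        raise AssertionError("disconnected")

    d = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(range(n_taxa), 2):
        d[a, b] = d[b, a] = path_length(a, b)

    def leaves_below(node, prev):
        if node < n_taxa:
            return {node}
        out = set()
        for nb, _ in adj[node]:
            if nb != prev:
                out |= leaves_below(nb, node)
        return out

    all_leaves = frozenset(range(n_taxa))
    truth = set()
    for node in adj:
        for nb, _ in adj[node]:
            if node < nb:
                side = frozenset(leaves_below(node, nb))
                if 0 in side:
                    side = all_leaves - side
                if 2 <= len(side) <= n_taxa - 2:
                    truth.add(frozenset(f"t{i}" for i in side))
    return d, truth


@pytest.fixture(scope="session")
def block_defs():
    return load_block_definitions()


@pytest.fixture(scope="session")
def canonical_core():
    """A noise-free consensus-instantiated 87-residue BSP core."""
    return prototype_core("BSP", "BSP1", seed=7)


@pytest.fixture(scope="session")
def small_panel():
    """A noise-free labelled panel covering all six lineages."""
    return generate_panel(default_panel_spec(seed=11, epsilon=0.0, per_group=2))
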