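import numpy as np
import pytest

from uoxcoopt import ancgain, kinetics


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) with unit-ish branch lengths."""
    return ancgain.Phylogeny.from_newick(
        "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1):0.0;"
    )


@pytest.fixture
def sixteen_leaf_tree():
    """Balanced-ish 14-leaf tree used for planted-history recovery."""
    nwk = ("((((A:0.04,B:0.04):0.04,(C:0.04,D:0.04):0.04):0.04,"
           "((E:0.04,F:0.04):0.04,(G:0.04,H:0.04):0.04):0.04):0.04,"
           "(((I:0.04,J:0.04):0.04,(K:0.04,L:0.04):0.04):0.04,"
           "(M:0.04,N:0.04):0.08):0.04);")
    return ancgain.Phylogeny.from_newick(nwk)


@pytest.fixture
def species_spectra():
    return kinetics.default_species_spectra()


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       with_lengths: bool = True) -> ancgain.Phylogeny:
    """Random rooted binary tree by sequential joining."""
    nodes = [ancgain.Node(label=chr(65 + i),
                          length=float(rng.uniform(0.05, 1.0)) if with_lengths else None)
             for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = ancgain.Node(
            label=f"I{counter}",
            length=float(rng.uniform(0.05, 1.0)) if with_lengths else None,
        )
        counter += 1
        parent.children = [left, right]
        left.parent = parent
        right.parent = parent
        nodes.append(parent)
    nodes[0].length = None
    return ancgain.Phylogeny(root=nodes[0])


def brute_force_parsimony(tree: ancgain.Phylogeny,
                          leaf_states: dict[str, int | None]) -> int:
    """Exhaustive minimum change count over all internal labelings."""
    import itertools

    internal = [n for n in tree.nodes() if not n.is_leaf]
    best = np.inf
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for label, node in tree.leaves.items():
            s = leaf_states.get(label)
            if s is not None:
                assign[node] = s
        changes = 0
        for parent, child in tree.branches():
            if child not in assign:  # masked leaf: free choice, pick parent state
                assign[child] = assign[parent]
            changes += assign[parent] != assign[child]
        best = min(best, changes)
    return int(best)


def brute_force_marginals(tree: ancgain.Phylogeny,
                          leaf_states: dict[str, int | None],
                          model: ancgain.TwoStateModel) -> dict:
    """Posterior of state 1 per node by exhaustive summation."""
    import itertools

    free = [n for n in tree.nodes()
            if not n.is_leaf or leaf_states.get(n.label) is None]
    prior = np.asarray(model.root_prior)
    weight = {n: 0.0 for n in tree.nodes()}
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(zip(free, combo))
        for label, node in tree.leaves.items():
            s = leaf_states.get(label)
            if s is not None:
                assign[node] = s
        p = prior[assign[tree.root]]
        for parent, child in tree.branches():
            p *= model.transition(child.length)[assign[parent], assign[child]]
        total += p
        for n in tree.nodes():
            weight[n] += p * assign[n]
    return {n: w / total for n, w in weight.items()}
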