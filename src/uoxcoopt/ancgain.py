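"""Ancestral cysteine gain/loss reconstruction on a rooted phylogeny.

Each alignment column is recoded as a binary character (target residue
present / absent; gaps and ambiguity letters masked) and reconstructed on a
given rooted tree under four schemes named after the options commonly
exposed by ancestral-reconstruction software:

* ``mpr`` — most-parsimonious reconstruction: per node, the set of states
  realizing the minimum change count (unit-cost Sankoff down/up pass);
* ``mpr_acctran`` — a single optimal labeling with changes accelerated
  toward the root (documented deterministic tie rule);
* ``ml`` — joint maximum-likelihood reconstruction under a two-state
  continuous-time Markov chain (max-product pruning);
* ``bayes`` — marginal highest-posterior state per node (sum-product
  pruning, one down pass and one up pass).

Per-branch gains (0 -> 1), losses (1 -> 0) and net enrichment (gain minus
loss) are then summed over columns. The identity that, for any column, the
net change along a root-to-leaf path equals leaf state minus root state is
asserted on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

from .orthocomp import AMINO_ACIDS

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Phylogeny",
    "ColumnStates",
    "TwoStateModel",
    "binarize_alignment",
    "fitch_mpr",
    "acctran_resolve",
    "ml_marginal",
    "ml_joint",
    "reconstruct",
    "branch_events",
]

_MASK_LETTERS = frozenset("-.XBZU*?")


@dataclass(eq=False)
class Node:
    """Lightweight rooted-tree node for the reconstruction dynamic programs."""

    label: str
    length: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)


@dataclass
class Phylogeny:
    """Rooted tree with uniquely labeled leaves.

    Built from a Newick string/file (via dendropy) or assembled directly.
    Internal nodes without labels get deterministic preorder names N0, N1...
    """

    root: Node
    leaves: dict[str, Node] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.leaves:
            self.leaves = {}
            for node in self.root.preorder():
                if node.is_leaf:
                    if node.label in self.leaves:
                        raise ValueError(f"duplicate leaf label {node.label!r}")
                    self.leaves[node.label] = node
        for node in self.root.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.label!r}")

    @classmethod
    def from_newick(cls, source: str, is_path: bool = False) -> "Phylogeny":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        counter = [0]

        def convert(dnode) -> Node:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            else:
                label = f"N{counter[0]}"
                counter[0] += 1
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                cn = convert(child)
                cn.parent = node
                node.children.append(cn)
            return node

        return cls(root=convert(tree.seed_node))

    def nodes(self) -> list[Node]:
        return list(self.root.preorder())

    def branches(self) -> list[tuple[Node, Node]]:
        return [(n.parent, n) for n in self.root.preorder() if n.parent is not None]

    def require_lengths(self) -> None:
        for parent, child in self.branches():
            if child.length is None:
                raise ValueError(
                    f"branch {parent.label}->{child.label} has no length"
                )


@dataclass
class ColumnStates:
    """Binary presence/absence of a target residue per alignment column x taxon.

    ``states[k, i]`` is 1 when taxon ``taxa[i]`` holds the target residue at
    column k, 0 for any other residue; ``mask[k, i]`` is True for gaps and
    ambiguity letters (state value is then meaningless).
    """

    taxa: list[str]
    states: np.ndarray  # (n_columns, n_taxa) uint8
    mask: np.ndarray  # (n_columns, n_taxa) bool
    residue: str = "C"

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.states.shape != self.mask.shape:
            raise ValueError("states and mask shapes differ")
        if self.states.shape[1] != len(self.taxa):
            raise ValueError("taxon count mismatch")

    @property
    def n_columns(self) -> int:
        return self.states.shape[0]

    def column(self, k: int) -> dict[str, int | None]:
        """Leaf states for column k; None for masked cells."""
        return {
            taxon: (None if self.mask[k, i] else int(self.states[k, i]))
            for i, taxon in enumerate(self.taxa)
        }


@dataclass
class TwoStateModel:
    """Two-state CTMC with gain rate alpha (0->1) and loss rate beta (1->0).

    The default root prior is the stationary distribution
    (beta, alpha)/(alpha+beta); pass ``root_prior=(0.5, 0.5)`` for a flat one.
    """

    alpha: float
    beta: float
    root_prior: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("rates must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValueError("total rate must be positive")
        if self.root_prior is None:
            total = self.alpha + self.beta
            self.root_prior = (self.beta / total, self.alpha / total)

    def transition(self, t: float) -> np.ndarray:
        """P[i, j] = Pr(state j at branch end | state i at branch start)."""
        total = self.alpha + self.beta
        e = np.exp(-total * t)
        p01 = self.alpha / total * (1 - e)
        p10 = self.beta / total * (1 - e)
        return np.array([[1 - p01, p01], [p10, 1 - p10]])


def binarize_alignment(alignment, residue: str = "C") -> ColumnStates:
    """Recode an alignment as presence/absence of one residue per column.

    ``alignment`` is a FASTA path or a mapping taxon -> aligned sequence.
    Gap and ambiguity characters (- . X B Z U * ?) are masked.
    """
    residue = residue.upper()
    if residue not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not a standard amino acid")
    if isinstance(alignment, dict):
        seqs = {k: v.upper() for k, v in alignment.items()}
    else:
        aln = AlignIO.read(str(alignment), "fasta")
        seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    if not seqs:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    taxa = list(seqs)
    ncol = lengths.pop()
    states = np.zeros((ncol, len(taxa)), dtype=np.uint8)
    mask = np.zeros((ncol, len(taxa)), dtype=bool)
    for i, taxon in enumerate(taxa):
        col = np.frombuffer(seqs[taxon].encode(), dtype="S1")
        states[:, i] = col == residue.encode()
        mask[:, i] = np.isin(col, [c.encode() for c in _MASK_LETTERS])
    states[mask] = 0
    return ColumnStates(taxa=taxa, states=states, mask=mask, residue=residue)


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------

def _subtree_costs(tree: Phylogeny, leaf_states: dict[str, int | None]) -> dict[Node, np.ndarray]:
    """Unit-cost Sankoff down pass: cost[node][s] = min changes in the subtree
    of ``node`` given node has state s. Masked leaves cost 0 in both states."""
    cost: dict[Node, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            state = leaf_states.get(node.label)
            if state is None:
                cost[node] = np.zeros(2)
            else:
                c = np.full(2, np.inf)
                c[state] = 0.0
                cost[node] = c
        else:
            c = np.zeros(2)
            for child in node.children:
                cc = cost[child]
                # moving parent state s to child state t costs [s != t]
                c += np.array([min(cc[0], cc[1] + 1), min(cc[0] + 1, cc[1])])
            cost[node] = c
    return cost


def fitch_mpr(tree: Phylogeny, leaf_states: dict[str, int | None]):
    """Most-parsimonious reconstruction of a binary column.

    Returns ``(score, state_sets, subtree_costs)`` where ``state_sets`` maps
    each node to exactly the states occurring in at least one minimum-change
    labeling (computed by combining subtree costs with outside costs), and
    ``score`` is that minimum change count. Masked leaves are uninformative
    ({0, 1}). Requires at least two unmasked leaves.
    """
    unmasked = [v for v in leaf_states.values() if v is not None]
    if len(unmasked) < 2:
        raise ValueError("need at least two unmasked leaves")
    down = _subtree_costs(tree, leaf_states)

    # outside cost: min changes outside the subtree of node, given node state
    up: dict[Node, np.ndarray] = {tree.root: np.zeros(2)}
    for node in tree.root.preorder():
        for child in node.children:
            sib_cost = np.zeros(2)
            for sib in node.children:
                if sib is child:
                    continue
                sc = down[sib]
                sib_cost += np.array([min(sc[0], sc[1] + 1), min(sc[0] + 1, sc[1])])
            parent_total = up[node] + sib_cost
            up[child] = np.array(
                [
                    min(parent_total[0], parent_total[1] + 1),
                    min(parent_total[0] + 1, parent_total[1]),
                ]
            )

    score = float(np.min(down[tree.root]))
    sets: dict[Node, set[int]] = {}
    for node in tree.root.preorder():
        total = down[node] + up[node]
        best = total.min()
        sets[node] = {s for s in (0, 1) if total[s] == best}
    return int(score), sets, down


def _resolve_optimal(tree: Phylogeny, mpr_state_sets: dict[Node, set[int]],
                     subtree_costs: dict[Node, np.ndarray], prefer_change: bool,
                     root_tie_state: int = 0) -> dict[Node, int]:
    """Pre-order resolution of MPR ambiguity into one optimal labeling.

    Each node takes the state minimizing (subtree cost) + (change from the
    parent's resolved state); that greedy choice always realizes the
    parsimony score. On ties, ``prefer_change`` selects the state differing
    from the parent (changes accelerated toward the root) or matching it
    (changes delayed toward the leaves). Root ties go to ``root_tie_state``.
    """
    states: dict[Node, int] = {}
    for node in tree.root.preorder():
        if not mpr_state_sets.get(node):
            raise RuntimeError(f"empty MPR state set at node {node.label!r}")
        if node.parent is None:
            c = subtree_costs[node]
            states[node] = root_tie_state if c[0] == c[1] else int(np.argmin(c))
        else:
            p = states[node.parent]
            c = subtree_costs[node]
            totals = {s: c[s] + (s != p) for s in (0, 1)}
            best = min(totals.values())
            candidates = [s for s in (0, 1) if totals[s] == best]
            if len(candidates) == 1:
                states[node] = candidates[0]
            else:
                states[node] = (1 - p) if prefer_change else p
    return states


def acctran_resolve(tree: Phylogeny, mpr_state_sets: dict[Node, set[int]],
                    subtree_costs: dict[Node, np.ndarray],
                    root_tie_state: int = 0) -> dict[Node, int]:
    """Accelerated-transformation labeling: ambiguity resolved toward change.

    Ambiguous nodes (visited in pre-order) prefer the state that differs from
    the parent's resolved state, placing changes as close to the root as
    possible; at the root, ties go to ``root_tie_state`` (absence by
    default). The labeling's change count equals the parsimony score.
    """
    return _resolve_optimal(tree, mpr_state_sets, subtree_costs,
                            prefer_change=True, root_tie_state=root_tie_state)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _partials(tree: Phylogeny, leaf_states: dict[str, int | None],
              model: TwoStateModel) -> dict[Node, np.ndarray]:
    """Sum-product down pass: L[node][s] = Pr(leaves below node | node = s)."""
    L: dict[Node, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            state = leaf_states.get(node.label)
            L[node] = np.ones(2) if state is None else np.eye(2)[state]
        else:
            part = np.ones(2)
            for child in node.children:
                P = model.transition(child.length)
                part = part * (P @ L[child])
            L[node] = part
    return L


def ml_marginal(tree: Phylogeny, leaf_states: dict[str, int | None],
                model: TwoStateModel) -> dict[Node, float]:
    """Marginal posterior probability of state 1 per node (sum-product pruning).

    One down pass of partial likelihoods, one up pass of above-partials;
    posterior(node = s) proportional to above[s] * below[s].
    """
    tree.require_lengths()
    if all(v is None for v in leaf_states.values()):
        raise ValueError("all leaves masked")
    L = _partials(tree, leaf_states, model)
    prior = np.asarray(model.root_prior)

    above: dict[Node, np.ndarray] = {tree.root: prior.copy()}
    for node in tree.root.preorder():
        for child in node.children:
            sib = np.ones(2)
            for other in node.children:
                if other is child:
                    continue
                P = model.transition(other.length)
                sib = sib * (P @ L[other])
            P = model.transition(child.length)
            above[child] = (above[node] * sib) @ P

    posteriors: dict[Node, float] = {}
    for node in tree.root.preorder():
        joint = above[node] * L[node]
        total = joint.sum()
        if total <= 0:
            raise ValueError("zero likelihood: inconsistent column")
        posteriors[node] = float(joint[1] / total)
    return posteriors


def ml_joint(tree: Phylogeny, leaf_states: dict[str, int | None],
             model: TwoStateModel) -> dict[Node, int]:
    """Joint maximum-likelihood reconstruction (max-product pruning + traceback)."""
    tree.require_lengths()
    if all(v is None for v in leaf_states.values()):
        raise ValueError("all leaves masked")
    M: dict[Node, np.ndarray] = {}
    back: dict[Node, np.ndarray] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            state = leaf_states.get(node.label)
            M[node] = np.ones(2) if state is None else np.eye(2)[state]
            back[node] = np.array([0, 1])
        else:
            m = np.ones(2)
            for child in node.children:
                P = model.transition(child.length)
                contrib = P * M[child][None, :]  # parent state x child state
                m = m * contrib.max(axis=1)
            M[node] = m
    prior = np.asarray(model.root_prior)
    states: dict[Node, int] = {}
    root_scores = prior * M[tree.root]
    states[tree.root] = int(np.argmax(root_scores))
    for node in tree.root.preorder():
        s = states[node]
        for child in node.children:
            P = model.transition(child.length)
            states[child] = int(np.argmax(P[s] * M[child]))
    # leaves keep their observed state where unmasked
    for label, node in tree.leaves.items():
        v = leaf_states.get(label)
        if v is not None:
            states[node] = v
    return states


# ---------------------------------------------------------------------------
# Reconstruction driver and event counting
# ---------------------------------------------------------------------------

def _column_assignment(tree: Phylogeny, leaf_states: dict[str, int | None],
                       method: str, model: TwoStateModel | None,
                       posterior_threshold: float) -> dict[Node, int] | None:
    unmasked = [v for v in leaf_states.values() if v is not None]
    if len(unmasked) < 2:
        return None
    if method not in ("mpr", "mpr_acctran", "ml", "bayes"):
        raise ValueError(f"unknown method {method!r}")
    if method in ("mpr", "mpr_acctran"):
        _, sets, down = fitch_mpr(tree, leaf_states)
        # plain mpr delays changes toward the leaves; acctran accelerates them
        return _resolve_optimal(tree, sets, down,
                                prefer_change=(method == "mpr_acctran"))
    if model is None:
        raise ValueError("probabilistic methods need a TwoStateModel")
    if method == "ml":
        return ml_joint(tree, leaf_states, model)
    if method == "bayes":
        post = ml_marginal(tree, leaf_states, model)
        states: dict[Node, int] = {}
        for node in tree.root.preorder():
            p1 = post[node]
            if p1 > posterior_threshold:
                states[node] = 1
            elif p1 < posterior_threshold:
                states[node] = 0
            else:  # exact tie: follow the parent (no event), root tie -> 0
                states[node] = states[node.parent] if node.parent else 0
        return states
    raise AssertionError("unreachable")


def reconstruct(tree: Phylogeny, columns: ColumnStates, method: str = "mpr_acctran",
                model: TwoStateModel | None = None,
                posterior_threshold: float = 0.5) -> list[dict[Node, int] | None]:
    """Fixed ancestral states per column; None for columns with <2 unmasked leaves."""
    assignments = []
    skipped = 0
    for k in range(columns.n_columns):
        leaf_states = columns.column(k)
        a = _column_assignment(tree, leaf_states, method, model, posterior_threshold)
        if a is None:
            skipped += 1
        assignments.append(a)
    if skipped:
        logger.warning("%d column(s) skipped: fewer than 2 unmasked leaves", skipped)
    return assignments


def branch_events(tree: Phylogeny, assignments: list[dict[Node, int] | None],
                  method: str = "", per_column: bool = False) -> pd.DataFrame:
    """Per-branch gains (0->1), losses (1->0) and net = gains - losses.

    Masked leaf cells do not generate events (the leaf takes its assigned
    reconstructed state only if the assignment includes it; for parsimony and
    joint ML, masked leaves are assigned, and events on their pendant
    branches count per the assignment). Asserts path conservation: per
    column, the net change along every root-to-leaf path equals the leaf
    state minus the root state.
    """
    branches = tree.branches()
    gains = {(p.label, c.label): 0 for p, c in branches}
    losses = {(p.label, c.label): 0 for p, c in branches}
    events = []
    for k, assignment in enumerate(assignments):
        if assignment is None:
            continue
        for parent, child in branches:
            if parent not in assignment or child not in assignment:
                raise ValueError(f"node missing a state in column {k}")
            ps, cs = assignment[parent], assignment[child]
            if ps == 0 and cs == 1:
                gains[(parent.label, child.label)] += 1
                if per_column:
                    events.append((k, parent.label, child.label, "gain"))
            elif ps == 1 and cs == 0:
                losses[(parent.label, child.label)] += 1
                if per_column:
                    events.append((k, parent.label, child.label, "loss"))
        # path conservation (exact bookkeeping identity)
        for leaf in tree.leaves.values():
            net = 0
            node = leaf
            while node.parent is not None:
                net += assignment[node] - assignment[node.parent]
                node = node.parent
            assert net == assignment[leaf] - assignment[tree.root]

    table = pd.DataFrame(
        [
            (p.label, c.label, gains[(p.label, c.label)], losses[(p.label, c.label)],
             gains[(p.label, c.label)] - losses[(p.label, c.label)], method)
            for p, c in branches
        ],
        columns=["parent_label", "child_label", "gains", "losses", "net", "method"],
    )
    if per_column:
        detail = pd.DataFrame(events, columns=["column", "parent_label",
                                               "child_label", "event"])
        return table, detail
    return table
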