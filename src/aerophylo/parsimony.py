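"""Unordered-parsimony ancestral-state reconstruction on rooted trees.

Characters are unordered: any change between distinct states costs one
step.  The reconstruction is Sankoff dynamic programming with the uniform
unit-cost matrix, which reduces to Fitch on binary trees and is
well-defined on polytomies (treated as hard multifurcations).  Missing
tips ('?') contribute zero cost to every state.  For each internal node
the full MPR (most-parsimonious-reconstruction) state set is reported --
the states attainable at that node under at least one minimum-change
assignment -- with no ACCTRAN/DELTRAN resolution imposed.

Trees and matrices are read from NEXUS (or newick for trees) via dendropy;
branch lengths are ignored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .characters import CharacterMatrix

__all__ = [
    "ReconstructionResult",
    "read_nexus",
    "parsimony_reconstruct",
    "exhaustive_parsimony_score",
    "summarize_mapping",
    "random_topology",
]

INF = float("inf")


@dataclass
class ReconstructionResult:
    """Per-character reconstruction: parsimony score and per-node MPR sets.

    Nodes are keyed canonically by the frozenset of descendant tip labels
    (a tip's key is ``frozenset({label})``), so results are invariant to
    tip-order permutations of the input tree.
    """

    character: str
    score: int
    mpr_sets: dict = field(default_factory=dict)
    node_keys: dict = field(default_factory=dict)  # readable name -> key

    def mpr(self, node) -> frozenset:
        """MPR set for a node given as a key, a readable name, or tip labels."""
        key = self._resolve(node)
        return self.mpr_sets[key]

    def resolved(self, node):
        """The state at a node when unique across all MPRs, else None."""
        s = self.mpr(node)
        return next(iter(s)) if len(s) == 1 else None

    def _resolve(self, node):
        if isinstance(node, frozenset):
            return node
        if isinstance(node, str):
            if node in self.node_keys:
                return self.node_keys[node]
            return frozenset({node})
        return frozenset(node)


def _leafset(node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def read_nexus(path, matrix_path=None):
    """Read a rooted phylogeny plus character matrix from NEXUS.

    ``path`` may hold both TREES and CHARACTERS blocks; otherwise pass the
    matrix file separately.  Newick tree files are accepted.  Taxa are
    cross-checked: every matrix taxon must map to exactly one tip.
    Returns ``(dendropy.Tree, CharacterMatrix)``.
    """
    path = str(path)
    try:
        ds = dendropy.DataSet.get(path=path, schema="nexus", preserve_underscores=True)
    except Exception:
        ds = dendropy.DataSet()
        ds.read(path=path, schema="newick", preserve_underscores=True)
    if not ds.tree_lists or not len(ds.tree_lists[0]):
        raise ValueError(f"no trees found in {path}")
    tree = ds.tree_lists[0][0]
    tree.is_rooted = True

    if matrix_path is not None:
        matrix = CharacterMatrix.from_nexus(matrix_path)
    elif ds.char_matrices:
        matrix = CharacterMatrix.from_nexus(path)
    else:
        raise ValueError("no character matrix supplied or found in the tree file")

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ValueError("tree has duplicate tip labels")
    missing = sorted(set(matrix.taxa) - set(tips))
    if missing:
        raise ValueError(f"matrix taxa absent from the tree: {missing}")
    return tree, matrix


def parsimony_reconstruct(tree: dendropy.Tree, char_states: dict, symbols,
                          character: str = "") -> ReconstructionResult:
    """Sankoff reconstruction of one character on a rooted tree.

    ``char_states`` maps tip label to a state symbol (or '?'); ``symbols``
    is the ordered state space.  Unknown symbols raise.
    """
    symbols = list(symbols)
    index = {s: i for i, s in enumerate(symbols)}
    k = len(symbols)
    for taxon, state in char_states.items():
        if state != "?" and state not in index:
            raise ValueError(f"unknown state symbol {state!r} for taxon {taxon!r}")

    down: dict = {}
    post = list(tree.postorder_node_iter())
    for node in post:
        if node.is_leaf():
            label = node.taxon.label
            if label not in char_states:
                raise ValueError(f"no state for tip {label!r}")
            state = char_states[label]
            if state == "?":
                down[node] = np.zeros(k)
            else:
                costs = np.full(k, INF)
                costs[index[state]] = 0.0
                down[node] = costs
        else:
            total = np.zeros(k)
            for child in node.child_nodes():
                c = down[child]
                # min over child state t of c[t] + (t != s)
                best = c.min()
                total += np.minimum(c, best + 1.0)
            down[node] = total

    root = tree.seed_node
    score = int(down[root].min())

    # cost of the rest of the tree conditional on each node's state
    up: dict = {root: np.zeros(k)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = node.parent_node
        base = up[parent].copy()
        for sib in parent.child_nodes():
            if sib is node:
                continue
            c = down[sib]
            best = c.min()
            base += np.minimum(c, best + 1.0)
        # up[node][s] = min_t base[t] + (t != s)
        best = base.min()
        up[node] = np.minimum(base, best + 1.0)

    mpr_sets, node_keys = {}, {}
    for node in post:
        key = _leafset(node)
        if node.is_leaf():
            state = char_states[node.taxon.label]
            mpr = frozenset(symbols) if state == "?" else frozenset({state})
            node_keys[node.taxon.label] = key
        else:
            total = down[node] + up[node]
            mpr = frozenset(symbols[i] for i in range(k) if total[i] == score)
            if node.label:
                node_keys[node.label] = key
        mpr_sets[key] = mpr
    return ReconstructionResult(character=character, score=score,
                                mpr_sets=mpr_sets, node_keys=node_keys)


def exhaustive_parsimony_score(tree: dendropy.Tree, char_states: dict, symbols) -> int:
    """Brute-force minimum number of state changes (reference implementation).

    Enumerates every assignment of states to internal nodes (and to '?'
    tips) and counts changes along edges.  Exponential; for small trees and
    use as an independent oracle in tests only.
    """
    symbols = list(symbols)
    nodes = list(tree.postorder_node_iter())
    free = [n for n in nodes
            if not n.is_leaf() or char_states[n.taxon.label] == "?"]
    fixed = {n: char_states[n.taxon.label] for n in nodes
             if n.is_leaf() and char_states[n.taxon.label] != "?"}
    best = INF
    for assignment in itertools.product(symbols, repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, assignment))
        changes = sum(
            1
            for n in nodes
            if n.parent_node is not None and state[n] != state[n.parent_node]
        )
        best = min(best, changes)
    return int(best)


def summarize_mapping(results: dict, named_nodes: dict, tree: dendropy.Tree) -> pd.DataFrame:
    """Tabulate reconstructed states at named nodes for every character.

    ``results`` maps character label to :class:`ReconstructionResult`;
    ``named_nodes`` maps a report name to either an internal-node label or
    a list of tip labels (the MRCA of those tips).  Returns a tidy frame
    with one row per (node, character): the MPR set (states joined by '|'),
    the unique state when unambiguous, and the parsimony score.
    """
    keys = {}
    labels = {n.label: n for n in tree.preorder_node_iter() if n.label}
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for name, spec in named_nodes.items():
        if isinstance(spec, str):
            if spec in labels:
                keys[name] = _leafset(labels[spec])
            elif spec in tip_labels:
                keys[name] = frozenset({spec})
            else:
                raise KeyError(f"unknown node name {spec!r}")
        else:
            tips = set(spec)
            unknown = tips - tip_labels
            if unknown:
                raise KeyError(f"unknown tip labels {sorted(unknown)}")
            mrca = tree.mrca(taxon_labels=sorted(tips))
            keys[name] = _leafset(mrca)
    rows = []
    for char, res in sorted(results.items()):
        for name, key in keys.items():
            states = sorted(res.mpr_sets[key])
            rows.append({
                "node": name,
                "character": char,
                "states": "|".join(states),
                "resolved": states[0] if len(states) == 1 else "",
                "score": res.score,
            })
    return pd.DataFrame(rows, columns=["node", "character", "states", "resolved", "score"])


def random_topology(tip_labels, rng: np.random.Generator,
                    polytomy_prob: float = 0.0) -> dendropy.Tree:
    """A uniform-ish random rooted topology over the given tips (no lengths).

    Built by random sequential joins; with ``polytomy_prob`` a join absorbs
    an extra subtree, producing multifurcations.  Intended for simulation
    and tests.
    """
    taxa = dendropy.TaxonNamespace(list(tip_labels))
    nodes = []
    for label in tip_labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    while len(nodes) > 1:
        n_join = 2
        if len(nodes) > 2 and rng.random() < polytomy_prob:
            n_join = 3
        picks = rng.choice(len(nodes), size=n_join, replace=False)
        parent = dendropy.Node()
        for i in sorted(picks, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree
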