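"""Tree inference and parsimony-based ancestral sequence sampling.

Trees are inferred by neighbor joining on Jukes-Cantor-corrected pairwise
distances and rooted at the midpoint; ties are broken deterministically by
sorting sequence names. Ancestral sequences are sampled per column by
Fitch parsimony with the gap as a fifth character state; among minimum-cost
assignments the sample follows Fitch's down-pass sets with randomized
tie-breaking.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import skbio

from .msa_io import Alignment, GAP_CODE

__all__ = [
    "TreeNode",
    "PhyloTree",
    "AncestralSample",
    "SubstitutionMap",
    "build_tree",
    "read_newick",
    "jukes_cantor_distances",
    "fitch_sample",
    "count_substitutions",
    "pair_substitution_counts",
]

#: distance assigned when the Jukes-Cantor correction diverges (p >= 3/4)
MAX_DISTANCE = 5.0

N_STATES = 5  # A C G U gap

_POPCOUNT = np.array([bin(m).count("1") for m in range(1 << N_STATES)], dtype=np.int64)
_BITS = np.zeros((1 << N_STATES, N_STATES), dtype=np.int8)
for _m in range(1, 1 << N_STATES):
    _bits = [b for b in range(N_STATES) if _m >> b & 1]
    _BITS[_m, : len(_bits)] = _bits
    _BITS[_m, len(_bits):] = _bits[0]


class TreeNode:
    """Rooted tree node; ``length`` is the branch length to the parent."""

    __slots__ = ("name", "length", "children", "parent", "index")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.index: int = -1

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()


@dataclass
class PhyloTree:
    """Rooted binary tree over the alignment's sequences.

    Nodes are indexed in postorder; a branch is identified by its child
    node's index. The root carries no branch.
    """

    root: TreeNode
    nodes: list[TreeNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = list(self.root.postorder())
        for idx, node in enumerate(self.nodes):
            node.index = idx

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_branches(self) -> int:
        return len(self.nodes) - 1

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.parent is None:
                return core
            return f"{core}:{node.length:.6g}"

        return render(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _from_skbio(sk_node) -> TreeNode:
    node = TreeNode(name=sk_node.name,
                    length=max(float(sk_node.length or 0.0), 0.0))
    for child in sk_node.children:
        node.add(_from_skbio(child))
    return node


def _binarize(node: TreeNode) -> None:
    """Resolve multifurcations into zero-length binary splits; drop unifurcations."""
    while len(node.children) == 1:
        only = node.children[0]
        node.name = node.name or only.name
        node.length += only.length
        node.children = only.children
        for c in node.children:
            c.parent = node
    while len(node.children) > 2:
        a = node.children.pop()
        b = node.children.pop()
        joint = TreeNode(length=0.0)
        joint.add(a)
        joint.add(b)
        node.add(joint)
    for child in node.children:
        _binarize(child)


def read_newick(path: str | Path) -> PhyloTree:
    sk = skbio.TreeNode.read(str(path))
    root = _from_skbio(sk)
    _binarize(root)
    return PhyloTree(root=root)


def jukes_cantor_distances(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """JC69-corrected pairwise distance matrix, names sorted for determinism."""
    order = sorted(range(aln.S), key=lambda k: aln.names[k])
    names = [aln.names[k] for k in order]
    codes = aln.codes()[order]
    occ = codes != GAP_CODE
    n = aln.S
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = occ[a] & occ[b]
            tot = int(both.sum())
            if tot == 0:
                d = MAX_DISTANCE
            else:
                p = float((codes[a][both] != codes[b][both]).sum()) / tot
                if p >= 0.749999:
                    d = MAX_DISTANCE
                else:
                    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dist[a, b] = dist[b, a] = d
    return dist, names


def build_tree(aln: Alignment, tree_path: Optional[str | Path] = None) -> PhyloTree:
    """Neighbor-joining tree with midpoint root (deterministic).

    A user-supplied Newick file overrides inference; its leaf names must
    match the alignment's names exactly.
    """
    if tree_path is not None:
        tree = read_newick(tree_path)
        if set(tree.leaf_names) != set(aln.names):
            raise ValueError("tree leaf names do not match alignment names")
        return tree
    if aln.S < 2:
        raise ValueError("tree inference needs at least 2 sequences")
    dist, names = jukes_cantor_distances(aln)
    if aln.S == 2:
        root = TreeNode()
        half = dist[0, 1] / 2.0
        for name in names:
            root.add(TreeNode(name=name, length=half))
        return PhyloTree(root=root)
    dm = skbio.DistanceMatrix(dist, ids=names)
    sk_tree = skbio.tree.nj(dm)
    try:
        sk_tree = sk_tree.root_at_midpoint()
    except Exception:
        # zero-length or degenerate trees: root on the first branch instead
        pass
    root = _from_skbio(sk_tree)
    _binarize(root)
    return PhyloTree(root=root)


@dataclass
class AncestralSample:
    """One Fitch-parsimony sample of all node sequences.

    ``node_codes`` maps node index -> (L,) int8 codes (gap = 4). Leaf rows
    equal the alignment rows. ``column_cost`` is the per-column parsimony
    minimum realized by the sample.
    """

    tree: PhyloTree
    node_codes: dict[int, np.ndarray]
    column_cost: np.ndarray
    seed: Optional[int] = None

    @property
    def total_cost(self) -> int:
        return int(self.column_cost.sum())


def _sample_bits(masks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    counts = _POPCOUNT[masks]
    k = np.floor(rng.random(masks.shape[0]) * counts).astype(np.int64)
    return _BITS[masks, k]


def fitch_sample(aln: Alignment, tree: PhyloTree,
                 seed: Optional[int | np.random.Generator] = None) -> AncestralSample:
    """Sample ancestral sequences achieving the per-column Fitch minimum."""
    if set(tree.leaf_names) != set(aln.names):
        raise ValueError("tree leaf names do not match alignment names")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = aln.codes()
    row_of = {name: r for r, name in enumerate(aln.names)}
    L = aln.L
    masks: dict[int, np.ndarray] = {}
    cost = np.zeros(L, dtype=np.int64)
    for node in tree.nodes:  # postorder
        if node.is_leaf:
            masks[node.index] = (np.uint8(1) << codes[row_of[node.name]].astype(np.uint8))
        else:
            child_masks = [masks[c.index] for c in node.children]
            inter = child_masks[0]
            union = child_masks[0]
            for m in child_masks[1:]:
                inter = inter & m
                union = union | m
            empty = inter == 0
            cost += empty
            masks[node.index] = np.where(empty, union, inter)
    node_codes: dict[int, np.ndarray] = {}
    for node in tree.root.preorder():
        mask = masks[node.index]
        if node.parent is None:
            node_codes[node.index] = _sample_bits(mask, rng)
        else:
            parent_states = node_codes[node.parent.index]
            keep = (mask >> parent_states.astype(np.uint8)) & 1
            sampled = _sample_bits(mask, rng)
            node_codes[node.index] = np.where(keep == 1, parent_states, sampled).astype(np.int8)
    return AncestralSample(tree=tree, node_codes=node_codes, column_cost=cost,
                           seed=None if isinstance(seed, np.random.Generator) else seed)


@dataclass
class SubstitutionMap:
    """Per-branch, per-column substitution events from an ancestral sample.

    ``events[b]`` lists (column, from_code, to_code) for branch ``b`` (child
    node index), including indel events (gap as fifth state).  ``per_branch``
    and ``per_column`` count residue-to-residue substitutions only — the
    counts used for covariation power, where indels carry no signal.
    """

    tree: PhyloTree
    L: int
    events: dict[int, list[tuple[int, int, int]]]
    per_branch: dict[int, int] = field(default_factory=dict)
    per_column: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.per_column is None:
            self.per_column = np.zeros(self.L, dtype=np.int64)
            for b, evs in self.events.items():
                n = 0
                for col, x, y in evs:
                    if x != GAP_CODE and y != GAP_CODE:
                        n += 1
                        self.per_column[col] += 1
                self.per_branch[b] = n

    @property
    def total(self) -> int:
        return int(self.per_column.sum())


def count_substitutions(sample: AncestralSample) -> SubstitutionMap:
    """Record every parent/child mismatch as a branch event."""
    tree = sample.tree
    L = sample.column_cost.shape[0]
    events: dict[int, list[tuple[int, int, int]]] = {}
    for node in tree.nodes:
        if node.parent is None:
            continue
        parent_seq = sample.node_codes[node.parent.index]
        child_seq = sample.node_codes[node.index]
        cols = np.nonzero(parent_seq != child_seq)[0]
        events[node.index] = [(int(c), int(parent_seq[c]), int(child_seq[c])) for c in cols]
    return SubstitutionMap(tree=tree, L=L, events=events)


def pair_substitution_counts(smap: SubstitutionMap, i: int, j: int) -> tuple[int, int]:
    """(single_subs, double_subs) for a column pair.

    single_subs sums the residue substitutions of the two columns;
    double_subs counts branches with at least one residue substitution in
    each column simultaneously.
    """
    if i == j:
        raise ValueError("pair requires two distinct columns")
    if not (0 <= i < smap.L and 0 <= j < smap.L):
        raise ValueError("column index out of range")
    single = int(smap.per_column[i] + smap.per_column[j])
    double = 0
    for evs in smap.events.values():
        hit_i = hit_j = False
        for col, x, y in evs:
            if x == GAP_CODE or y == GAP_CODE:
                continue
            if col == i:
                hit_i = True
            elif col == j:
                hit_j = True
        if hit_i and hit_j:
            double += 1
    return single, double
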