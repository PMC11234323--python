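"""Synthetic alignments: tree-structured simulation with base-pair
constraints, plus generators for the artifact scenarios (occupancy bias,
conserved-column traps, pseudogene mixtures, shifted helices).

Paired columns evolve jointly: a pair event proposes a double-compensatory
change (both partners change, pairing kept) with weight 0.8, a
half-compensatory change (one partner, pairing kept, G:U allowed) with
weight 0.15, and a pair-breaking change with weight 0.05 by default.
Unpaired columns evolve independently under a Jukes-Cantor-like process.
Branch lengths are expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .msa_io import Alignment, ConsensusStructure, make_structure
from .phylo import PhyloTree, TreeNode

__all__ = [
    "SimConfig",
    "random_tree",
    "simulate_structural_alignment",
    "make_gap_bias_scenario",
    "make_conserved_column_trap",
    "make_pseudogene_mixture",
    "make_misaligned_helix",
]

_CANONICAL = [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]  # AU UA CG GC GU UG
_WATSON_CRICK = [(0, 3), (3, 0), (1, 2), (2, 1)]
_ALL_PAIRS = [(a, b) for a in range(4) for b in range(4)]
_NONCANONICAL = [p for p in _ALL_PAIRS if p not in _CANONICAL]
_COMP = {0: 3, 3: 0, 1: 2, 2: 1}
_ALPHABET = np.frombuffer(b"ACGU-", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one simulated alignment."""

    S: int = 20
    L: int = 100
    branch_length: float = 0.3
    n_pairs: int = 0
    pairs: Optional[Sequence[tuple[int, int]]] = None
    #: (double-compensatory, half-compensatory, pair-breaking) proposal weights
    kernel: tuple[float, float, float] = (0.8, 0.15, 0.05)
    #: per-column gap probability applied i.i.d. at the leaves
    gap_profile: Optional[np.ndarray] = None
    pseudogene_fraction: float = 0.0
    #: rate multiplier on unconstrained (pseudogene) lineages
    pseudogene_rate: float = 2.0
    tree: Optional[PhyloTree] = None
    seed: Optional[int] = None

    def resolved_pairs(self) -> list[tuple[int, int]]:
        if self.pairs is not None:
            pairs = [tuple(sorted(p)) for p in self.pairs]
        else:
            pairs = [(k, self.L - 1 - k) for k in range(self.n_pairs)]
        for i, j in pairs:
            if not (0 <= i < j < self.L):
                raise ValueError(f"structure pair ({i}, {j}) outside alignment")
        if self.pseudogene_fraction < 0 or self.pseudogene_fraction > 1:
            raise ValueError("pseudogene fraction must be in [0, 1]")
        return pairs


def random_tree(S: int, branch_length: float = 0.3,
                seed: Optional[int | np.random.Generator] = None) -> PhyloTree:
    """Random binary topology by uniform coalescent-style joining."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [TreeNode(name=f"seq{k + 1}", length=branch_length) for k in range(S)]
    if S == 1:
        return PhyloTree(root=nodes[0])
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=branch_length)
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(length=0.0)
    root.add(nodes[0])
    root.add(nodes[1])
    return PhyloTree(root=root)


def two_clade_tree(S: int, stem: float = 2.0, leaf: float = 0.02) -> PhyloTree:
    """Two balanced clades separated by long stem branches.

    This topology maximizes phylogenetic covariation: substitutions on the
    stems are co-inherited by whole clades, so unrelated column pairs show
    strong clade-contrast co-dependence.
    """
    root = TreeNode()
    names = iter(f"seq{k + 1}" for k in range(S))
    for _ in range(2):
        nodes = [TreeNode(name=next(names), length=leaf) for _ in range(S // 2)]
        while len(nodes) > 1:
            parent = TreeNode(length=leaf)
            parent.add(nodes.pop())
            parent.add(nodes.pop())
            nodes.append(parent)
        nodes[0].length += stem
        root.add(nodes[0])
    return PhyloTree(root=root)


def star_tree(S: int, branch_length: float = 0.3) -> PhyloTree:
    """Binary pseudo-star: zero-length internal branches, leaves at depth t."""
    nodes = [TreeNode(name=f"seq{k + 1}", length=branch_length) for k in range(S)]
    while len(nodes) > 1:
        merged = []
        for k in range(0, len(nodes) - 1, 2):
            parent = TreeNode(length=0.0)
            parent.add(nodes[k])
            parent.add(nodes[k + 1])
            merged.append(parent)
        if len(nodes) % 2:
            merged.append(nodes[-1])
        nodes = merged
    return PhyloTree(root=nodes[0])


def _mutate_unpaired(seq: np.ndarray, cols: np.ndarray, p: float,
                     rng: np.random.Generator) -> None:
    hit = cols[rng.random(cols.size) < p]
    for c in hit:
        seq[c] = (seq[c] + rng.integers(1, 4)) % 4


def _propose_pair(cur: tuple[int, int], kernel: tuple[float, float, float],
                  rng: np.random.Generator) -> tuple[int, int]:
    weights = np.asarray(kernel, dtype=float)
    weights = weights / weights.sum()
    for cat in rng.choice(3, size=3, replace=False, p=weights):
        if cat == 0:
            options = [p for p in _CANONICAL if p[0] != cur[0] and p[1] != cur[1]]
        elif cat == 1:
            options = [p for p in _CANONICAL
                       if (p[0] != cur[0]) != (p[1] != cur[1])]
        else:
            options = [p for p in _NONCANONICAL if p != cur]
        if options:
            return options[int(rng.integers(len(options)))]
    return cur


def simulate_structural_alignment(config: SimConfig,
                                  ) -> tuple[Alignment, ConsensusStructure]:
    """Simulate an alignment along a tree; returns it with the truth pairs.

    The returned alignment carries the constrained pair set as its
    consensus structure (the truth labels).
    """
    rng = np.random.default_rng(config.seed)
    pairs = config.resolved_pairs()
    tree = config.tree or random_tree(config.S, config.branch_length, rng)
    leaves = tree.leaves
    if len(leaves) != config.S and config.tree is None:
        raise ValueError("tree size mismatch")
    paired_cols = {c for p in pairs for c in p}
    unpaired = np.array([c for c in range(config.L) if c not in paired_cols],
                        dtype=np.int64)
    pseudo_leaves: set[int] = set()
    if config.pseudogene_fraction > 0:
        k = int(round(config.pseudogene_fraction * len(leaves)))
        chosen = rng.choice(len(leaves), size=k, replace=False)
        pseudo_leaves = {leaves[int(c)].index for c in chosen}

    def subtree_is_pseudo(node: TreeNode) -> bool:
        tips = [n.index for n in node.postorder() if n.is_leaf]
        return bool(tips) and all(ix in pseudo_leaves for ix in tips)

    root_seq = rng.integers(0, 4, size=config.L).astype(np.int8)
    for i, j in pairs:
        a, b = _WATSON_CRICK[int(rng.integers(len(_WATSON_CRICK)))]
        root_seq[i], root_seq[j] = a, b
    seqs: dict[int, np.ndarray] = {tree.root.index: root_seq}
    for node in tree.root.preorder():
        if node.parent is None:
            continue
        seq = seqs[node.parent.index].copy()
        t = node.length
        unconstrained = config.pseudogene_fraction > 0 and subtree_is_pseudo(node)
        if unconstrained:
            t_eff = t * config.pseudogene_rate
            p = 1.0 - np.exp(-t_eff)
            _mutate_unpaired(seq, np.arange(config.L), p, rng)
        else:
            p = 1.0 - np.exp(-t)
            _mutate_unpaired(seq, unpaired, p, rng)
            for i, j in pairs:
                if rng.random() < p:
                    a, b = _propose_pair((int(seq[i]), int(seq[j])),
                                         config.kernel, rng)
                    seq[i], seq[j] = a, b
        seqs[node.index] = seq
    rows = {}
    for leaf in leaves:
        seq = seqs[leaf.index].copy()
        if config.gap_profile is not None:
            profile = np.asarray(config.gap_profile, dtype=float)
            gap = rng.random(config.L) < profile
            seq[gap] = 4
        rows[leaf.name] = _ALPHABET[seq.astype(np.int64)].tobytes().decode("ascii")
    names = sorted(rows)
    structure = make_structure(pairs) if pairs else ConsensusStructure(frozenset())
    aln = Alignment(names=names, rows=[rows[n] for n in names],
                    structure=structure if pairs else None)
    return aln, structure


def make_gap_bias_scenario(config: SimConfig, gap_rate: float = 0.35) -> Alignment:
    """Structure-free alignment whose left half has low occupancy.

    Gap probability is ``gap_rate`` on the left half of the columns and 0
    on the right half, reproducing the occupancy gradient that misleads
    occupancy-sensitive statistics (raw G-test) when the nulls do not
    preserve the gap structure. Unless a tree is supplied the sequences
    evolve on a deep two-clade topology, whose co-inherited stem
    substitutions provide the phylogenetic covariation the artifact needs.
    """
    profile = np.zeros(config.L)
    profile[: config.L // 2] = gap_rate
    tree = config.tree or two_clade_tree(config.S)
    cfg = replace(config, n_pairs=0, pairs=None, gap_profile=profile,
                  pseudogene_fraction=0.0, tree=tree)
    aln, _ = simulate_structural_alignment(cfg)
    return aln


def make_conserved_column_trap(config: SimConfig,
                               n_trap_pairs: int = 5,
                               ) -> tuple[Alignment, ConsensusStructure]:
    """Variable alignment with proposed pairs of fully conserved columns.

    Each proposed pair is Watson-Crick complementary and completely
    invariant, so MI is exactly 0 there; conservation-blind statistics must
    not call them significant, while conservation-rewarding scores (RAF)
    reproduce the artifact against conservation-destroying nulls.
    """
    cfg = replace(config, n_pairs=0, pairs=None, gap_profile=None,
                  pseudogene_fraction=0.0)
    aln, _ = simulate_structural_alignment(cfg)
    rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    pairs = [(k, config.L - 1 - k) for k in range(n_trap_pairs)]
    rows = [list(r) for r in aln.rows]
    letters = "ACGU"
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    for i, j in pairs:
        a = letters[int(rng.integers(4))]
        for row in rows:
            row[i] = a
            row[j] = comp[a]
    structure = make_structure(pairs)
    out = Alignment(names=list(aln.names), rows=["".join(r) for r in rows],
                    structure=structure)
    return out, structure


def make_pseudogene_mixture(config: SimConfig, fraction: Optional[float] = None,
                            ) -> tuple[Alignment, ConsensusStructure, list[str]]:
    """Structural alignment diluted with unconstrained (pseudogene) lineages.

    Returns the alignment, the truth pairs, and the pseudogene sequence
    names. Pseudogene lineages evolve every column independently at an
    elevated rate, adding substitutions (power) without compensation
    (covariation).
    """
    if fraction is not None:
        config = replace(config, pseudogene_fraction=fraction)
    rng = np.random.default_rng(config.seed)
    tree = config.tree or random_tree(config.S, config.branch_length, rng)
    cfg = replace(config, tree=tree, seed=None if config.seed is None
                  else config.seed + 7)
    aln, structure = simulate_structural_alignment(cfg)
    # recover which leaves were drawn as pseudogenes by rerunning the draw
    rng2 = np.random.default_rng(cfg.seed)
    leaves = tree.leaves
    labels: list[str] = []
    if cfg.pseudogene_fraction > 0:
        k = int(round(cfg.pseudogene_fraction * len(leaves)))
        chosen = rng2.choice(len(leaves), size=k, replace=False)
        labels = sorted(leaves[int(c)].name for c in chosen)
    return aln, structure, labels


def make_misaligned_helix(config: SimConfig, helix_len: int = 6,
                          shifted_fraction: float = 0.5,
                          ) -> tuple[Alignment, Alignment]:
    """(misaligned, corrected) alignments sharing one conserved helix.

    In the corrected alignment the helix is perfectly conserved: no
    covariation, maximal column conservation. The misaligned version shifts
    the helix of a subset of rows by one base pair — both partners move
    together, so every pair column shows two complementary states and
    spurious covariation appears while sequence identity drops.
    """
    rng = np.random.default_rng(config.seed)
    cfg = replace(config, n_pairs=0, pairs=None, gap_profile=None,
                  pseudogene_fraction=0.0,
                  seed=None if config.seed is None else config.seed + 3)
    base, _ = simulate_structural_alignment(cfg)
    L, S = config.L, base.S
    k = helix_len
    lb = L // 4
    rb = 3 * L // 4 - k
    if lb + k >= rb:
        raise ValueError("alignment too short for the helix blocks")
    # conserved helix residues; adjacent residues differ so a shift changes columns
    letters = "ACGU"
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    helix = []
    prev = None
    for _ in range(k + 1):  # one extra residue feeds the shifted register
        choices = [c for c in letters if c != prev]
        prev = choices[int(rng.integers(len(choices)))]
        helix.append(prev)
    pairs = [(lb + m, rb + k - 1 - m) for m in range(k)]
    shifted_rows = set(range(0, S, max(1, int(round(1 / shifted_fraction)))))

    def build(shift_rows: set[int]) -> Alignment:
        rows = []
        for r, row in enumerate(base.rows):
            chars = list(row)
            off = 1 if r in shift_rows else 0
            for m in range(k):
                res = helix[m + off]
                i, j = pairs[m]
                chars[i] = res
                chars[j] = comp[res]
            rows.append("".join(chars))
        return Alignment(names=list(base.names), rows=rows,
                         structure=make_structure(pairs))

    corrected = build(set())
    misaligned = build(shifted_rows)
    return misaligned, corrected


def calibrate_power_curves(seed: Optional[int] = None,
                           branch_lengths: Sequence[float] = tuple(
                               float(b) for b in np.linspace(0.05, 0.7, 14)),
                           replicates: int = 3, S: int = 40, L: int = 80,
                           n_pairs: int = 10, n_nulls: int = 20,
                           ) -> tuple["PowerCurve", "PowerCurve"]:
    """Fit single- and double-substitution power curves on simulations.

    Runs the full significance pipeline on structure-constrained
    simulations across a divergence range and fits isotonic detection
    curves on the true pairs. This is how the shipped default curves were
    produced (seed 0).
    """
    from . import evidence as _evidence
    from .nullgen import null_ensemble
    from .phylo import (build_tree, count_substitutions, fitch_sample,
                        pair_substitution_counts)

    rng = np.random.SeedSequence(seed)
    singles: list[tuple[int, bool]] = []
    doubles: list[tuple[int, bool]] = []
    children = iter(rng.spawn(len(branch_lengths) * replicates))
    for bl in branch_lengths:
        for _ in range(replicates):
            s = int(next(children).generate_state(1)[0]) % (2 ** 31)
            cfg = SimConfig(S=S, L=L, branch_length=float(bl), n_pairs=n_pairs,
                            seed=s)
            aln, truth = simulate_structural_alignment(cfg)
            tree = build_tree(aln)
            nulls = null_ensemble(aln, tree, n_nulls, seed=s + 1)
            sig = {(p.i, p.j) for p in _evidence.significant_pairs(aln, nulls)}
            smap = count_substitutions(fitch_sample(aln, tree, s + 2))
            for i, j in sorted(truth.pairs):
                sgl, dbl = pair_substitution_counts(smap, i, j)
                singles.append((sgl, (i, j) in sig))
                doubles.append((dbl, (i, j) in sig))
    curve_s = _evidence.fit_power_curve(singles, mode="single",
                                        source="synthetic-calibration")
    curve_d = _evidence.fit_power_curve(doubles, mode="double",
                                        source="synthetic-calibration")
    return curve_s, curve_d
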