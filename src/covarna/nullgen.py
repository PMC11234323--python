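"""Phylogenetic null alignments.

A null alignment carries the same per-branch substitution events as the
input alignment (as reconstructed by a fresh Fitch ancestral sample), but
every residue substitution is re-placed at a random eligible position of
the evolving null sequence. Because an event x -> y is always applied at a
position currently holding x, per-sequence residue composition is
preserved; because events are applied sequentially down the tree,
clade-inherited (phylogenetic) covariation survives while site-specific
covariation is destroyed.

Two modes:

* gap-preserving (default): indel events stay at their original columns,
  so every null row has exactly the source row's gap mask, and residue
  events are only re-placed among non-gap columns of the lineage.
* legacy: the gap is treated as a fifth character and all events
  (including indels) are re-placed, scrambling the occupancy profile. This
  mode reproduces the occupancy artifact that fools occupancy-sensitive
  statistics such as the G-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .msa_io import Alignment, GAP_CODE
from .phylo import PhyloTree, count_substitutions, fitch_sample

__all__ = ["NullAlignment", "synthesize_null", "null_ensemble"]


@dataclass
class NullAlignment:
    """An Alignment plus provenance of the null synthesis."""

    alignment: Alignment
    gap_preserving: bool
    sample_seed: Optional[int] = None
    placement_seed: Optional[int] = None
    #: events whose composition guarantee had to be relaxed (no position
    #: holding the source residue was available)
    fallback_events: int = 0
    #: per-branch event counts of the ancestral sample this null was built from
    branch_events_source: dict[int, int] = None
    #: per-branch parent/child differences realized in the null
    branch_events_null: dict[int, int] = None


def _codes_to_row(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGU-", dtype=np.uint8)
    return lut[codes.astype(np.int64)].tobytes().decode("ascii")


def synthesize_null(aln: Alignment, tree: PhyloTree,
                    seed: Optional[int | np.random.Generator] = None,
                    gap_preserving: bool = True) -> NullAlignment:
    """Synthesize one null alignment from a fresh ancestral sample."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample = fitch_sample(aln, tree, rng)
    smap = count_substitutions(sample)
    L = aln.L
    # Columns with any indel event in this sample are pinned to the source
    # history in gap-preserving mode: every event there (indel or residue)
    # is applied at its original column, which keeps gap masks, per-branch
    # event counts, and per-sequence composition exact simultaneously.
    pinned = np.zeros(L, dtype=bool)
    if gap_preserving:
        for evs in smap.events.values():
            for col, x, y in evs:
                if x == GAP_CODE or y == GAP_CODE:
                    pinned[col] = True
    null_codes: dict[int, np.ndarray] = {
        tree.root.index: sample.node_codes[tree.root.index].copy()
    }
    fallbacks = 0
    events_source: dict[int, int] = {}
    events_null: dict[int, int] = {}
    for node in tree.root.preorder():
        if node.parent is None:
            continue
        seq = null_codes[node.parent.index].copy()
        events = smap.events.get(node.index, [])
        touched = np.zeros(L, dtype=bool)
        if gap_preserving:
            for col, x, y in events:
                if pinned[col]:
                    seq[col] = y
                    touched[col] = True
        for col, x, y in events:
            if gap_preserving and pinned[col]:
                continue
            eligible = (seq == x) & ~touched
            if gap_preserving:
                eligible &= ~pinned & (seq != GAP_CODE)
            pos = np.nonzero(eligible)[0]
            if pos.size == 0:
                fallback = (seq != y) & ~touched & (seq != GAP_CODE)
                if gap_preserving:
                    fallback &= ~pinned
                pos = np.nonzero(fallback)[0]
                if pos.size == 0:
                    continue  # nothing to substitute; event dropped
                fallbacks += 1
            p = int(pos[rng.integers(pos.size)])
            seq[p] = y
            touched[p] = True
        null_codes[node.index] = seq
        events_source[node.index] = len(events)
        events_null[node.index] = int((seq != null_codes[node.parent.index]).sum())
    names = list(aln.names)
    row_codes = {n.name: null_codes[n.index] for n in tree.leaves}
    rows = [_codes_to_row(row_codes[name]) for name in names]
    null = Alignment(names=names, rows=rows, structure=aln.structure)
    return NullAlignment(alignment=null, gap_preserving=gap_preserving,
                         sample_seed=sample.seed, fallback_events=fallbacks,
                         branch_events_source=events_source,
                         branch_events_null=events_null)


def null_ensemble(aln: Alignment, tree: PhyloTree, n_nulls: int = 20,
                  seed: Optional[int] = None,
                  gap_preserving: bool = True) -> list[NullAlignment]:
    """Generate ``n_nulls`` independent null alignments from a master seed.

    Each null draws its own ancestral sample; the ensemble is reproducible
    from the master seed.
    """
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    master = np.random.SeedSequence(seed)
    out = []
    for child in master.spawn(n_nulls):
        rng = np.random.default_rng(child)
        out.append(synthesize_null(aln, tree, rng, gap_preserving=gap_preserving))
    return out
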