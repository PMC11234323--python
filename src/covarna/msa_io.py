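"""Alignment input/output, validation, and per-column summaries.

Alignments are RNA multiple sequence alignments over ``{A, C, G, U, -}``.
``T`` is normalized to ``U`` on input; IUPAC ambiguity codes and lowercase
residues are accepted but treated as missing data (gaps) by every counting
routine. Consensus secondary structures are parsed from Stockholm
``#=GC SS_cons`` lines in WUSS notation.

Coordinates are 0-based half-open internally; user-facing reports are
1-based.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import AlignIO

__all__ = [
    "Alignment",
    "ConsensusStructure",
    "ColumnProfile",
    "AlignmentFormatError",
    "read_alignment",
    "write_alignment",
    "parse_wuss",
    "structure_to_wuss",
    "average_pairwise_identity",
    "column_profiles",
    "pair_counts",
]

RESIDUES = "ACGU"
GAP = "-"
#: characters normalized to '-'
GAP_CHARS = set("-._~")
#: IUPAC ambiguity codes, treated as missing for counting
AMBIGUITY = set("RYSWKMBDHVN")
#: integer codes: A=0 C=1 G=2 U=3 gap/ambiguous=4
GAP_CODE = 4

_CODE_OF = {c: i for i, c in enumerate(RESIDUES)}

# WUSS bracket alphabets; uppercase letters open pseudoknotted helices,
# lowercase letters close them.
_OPEN = "<([{"
_CLOSE = ">)]}"


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, duplicate names, or unknown characters."""


@dataclass(frozen=True)
class ConsensusStructure:
    """A consensus secondary structure as a set of 0-based column pairs.

    ``pairs`` holds all base pairs (i, j) with i < j.  ``pseudoknot_pairs``
    is the subset annotated with WUSS letter (non-nested) alphabets.
    ``short_range_pairs`` is the subset with fewer than three unpaired
    nucleotides between the partners (j - i <= 3); such pairs are accepted
    but flagged because canonical Watson-Crick helices require the larger
    separation.
    """

    pairs: frozenset[tuple[int, int]]
    pseudoknot_pairs: frozenset[tuple[int, int]] = frozenset()
    short_range_pairs: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        seen: dict[int, tuple[int, int]] = {}
        for i, j in sorted(self.pairs):
            if not (0 <= i < j):
                raise ValueError(f"invalid pair ({i}, {j})")
            for k in (i, j):
                if k in seen:
                    raise ValueError(
                        f"column {k} participates in two pairs {seen[k]} and {(i, j)}"
                    )
                seen[k] = (i, j)

    @property
    def long_range_pairs(self) -> frozenset[tuple[int, int]]:
        return frozenset(p for p in self.pairs if p not in self.short_range_pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _flag_short(pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    return frozenset((i, j) for i, j in pairs if j - i <= 3)


def make_structure(pairs: Iterable[tuple[int, int]],
                   pseudoknot: Iterable[tuple[int, int]] = ()) -> ConsensusStructure:
    """Build a ConsensusStructure, auto-flagging short-range pairs."""
    ps = frozenset(tuple(sorted(p)) for p in pairs)
    return ConsensusStructure(
        pairs=ps,
        pseudoknot_pairs=frozenset(tuple(sorted(p)) for p in pseudoknot),
        short_range_pairs=_flag_short(ps),
    )


@dataclass
class Alignment:
    """A validated multiple sequence alignment.

    Rows are upper-case strings of equal length over the residue, gap and
    ambiguity alphabets. ``structure`` optionally carries the consensus
    secondary structure.
    """

    names: list[str]
    rows: list[str]
    structure: Optional[ConsensusStructure] = None
    _codes: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentFormatError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise AlignmentFormatError(f"duplicate sequence names: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"ragged alignment, row lengths {sorted(lengths)}")
        normalized = []
        bad: set[str] = set()
        for row in self.rows:
            out = []
            for ch in row.upper():
                if ch == "T":
                    ch = "U"
                elif ch in GAP_CHARS:
                    ch = GAP
                if ch not in _CODE_OF and ch != GAP and ch not in AMBIGUITY:
                    bad.add(ch)
                out.append(ch)
            normalized.append("".join(out))
        if bad:
            raise AlignmentFormatError(f"unknown characters in alignment: {sorted(bad)}")
        self.rows = normalized
        if self.structure is not None and self.structure.pairs:
            jmax = max(j for _, j in self.structure.pairs)
            if jmax >= self.L:
                raise AlignmentFormatError("structure pair index beyond alignment length")

    @property
    def S(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def codes(self) -> np.ndarray:
        """(S, L) int8 matrix: A=0 C=1 G=2 U=3, gap/ambiguous=4."""
        if self._codes is None:
            lut = np.full(128, GAP_CODE, dtype=np.int8)
            for c, i in _CODE_OF.items():
                lut[ord(c)] = i
            mat = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.S, self.L)
            self._codes = lut[mat]
        return self._codes

    def gap_mask(self) -> np.ndarray:
        """(S, L) bool, True where a row is gapped/ambiguous."""
        return self.codes() == GAP_CODE

    def replace(self, **kw) -> "Alignment":
        data = {"names": list(self.names), "rows": list(self.rows),
                "structure": self.structure}
        data.update(kw)
        return Alignment(**data)


def parse_wuss(ss: str) -> ConsensusStructure:
    """Parse a WUSS/dot-bracket consensus structure string into pairs.

    All four bracket alphabets are accepted; uppercase/lowercase letter
    pairs are stored as pseudoknot pairs. Pairs separated by three or fewer
    positions are kept but flagged (``short_range_pairs``) with a warning.
    """
    stacks: dict[str, list[int]] = {o: [] for o in _OPEN}
    letters: dict[str, list[int]] = {}
    pairs: set[tuple[int, int]] = set()
    pk: set[tuple[int, int]] = set()
    for idx, ch in enumerate(ss):
        if ch in _OPEN:
            stacks[ch].append(idx)
        elif ch in _CLOSE:
            opener = _OPEN[_CLOSE.index(ch)]
            if not stacks[opener]:
                raise AlignmentFormatError(f"unbalanced '{ch}' at column {idx} in SS_cons")
            pairs.add((stacks[opener].pop(), idx))
        elif ch.isalpha():
            if ch.isupper():
                letters.setdefault(ch, []).append(idx)
            else:
                up = ch.upper()
                if not letters.get(up):
                    raise AlignmentFormatError(
                        f"unbalanced pseudoknot '{ch}' at column {idx} in SS_cons")
                i = letters[up].pop()
                pairs.add((i, idx))
                pk.add((i, idx))
        # everything else (.,:_-~ etc.) is unpaired
    for stack in stacks.values():
        if stack:
            raise AlignmentFormatError("unbalanced open bracket in SS_cons")
    for up, stack in letters.items():
        if stack:
            raise AlignmentFormatError(f"unbalanced pseudoknot letter '{up}' in SS_cons")
    short = _flag_short(pairs)
    if short:
        warnings.warn(
            f"{len(short)} consensus pair(s) separated by <=3 columns; flagged",
            stacklevel=2,
        )
    return ConsensusStructure(pairs=frozenset(pairs),
                              pseudoknot_pairs=frozenset(pk),
                              short_range_pairs=short)


def structure_to_wuss(structure: ConsensusStructure, L: int) -> str:
    """Render pairs as dot-bracket WUSS; pseudoknot pairs use Aa letters."""
    out = ["."] * L
    for i, j in sorted(structure.pairs - structure.pseudoknot_pairs):
        out[i], out[j] = "<", ">"
    for k, (i, j) in enumerate(sorted(structure.pseudoknot_pairs)):
        letter = chr(ord("A") + (k % 26))
        out[i], out[j] = letter, letter.lower()
    return "".join(out)


def read_alignment(path: str | Path, fmt: Optional[str] = None) -> Alignment:
    """Read a Stockholm or aligned-FASTA alignment.

    ``fmt`` is ``"stockholm"`` or ``"afa"``; when omitted it is guessed from
    the first byte ('#' or '>').
    """
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        head = text.lstrip()[:1]
        fmt = "stockholm" if head == "#" else "afa"
    if fmt not in ("stockholm", "afa"):
        raise ValueError(f"unknown alignment format {fmt!r}")
    bio_fmt = "stockholm" if fmt == "stockholm" else "fasta"
    try:
        msa = AlignIO.read(io.StringIO(text), bio_fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    names = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    structure = None
    ss = msa.column_annotations.get("secondary_structure") if fmt == "stockholm" else None
    if ss:
        structure = parse_wuss(ss)
    return Alignment(names=names, rows=rows, structure=structure)


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "stockholm",
                    comments: Optional[dict[str, str]] = None) -> None:
    """Write Stockholm (with SS_cons when a structure is present) or FASTA."""
    path = Path(path)
    if fmt == "afa":
        with path.open("w") as fh:
            for name, row in zip(aln.names, aln.rows):
                fh.write(f">{name}\n{row}\n")
        return
    if fmt != "stockholm":
        raise ValueError(f"unknown alignment format {fmt!r}")
    width = max(len(n) for n in aln.names)
    width = max(width, len("#=GC SS_cons"))
    with path.open("w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for key, value in (comments or {}).items():
            fh.write(f"#=GF {key} {value}\n")
        for name, row in zip(aln.names, aln.rows):
            fh.write(f"{name:<{width}} {row}\n")
        if aln.structure is not None:
            fh.write(f"{'#=GC SS_cons':<{width}} {structure_to_wuss(aln.structure, aln.L)}\n")
        fh.write("//\n")


def average_pairwise_identity(aln: Alignment) -> float:
    """Mean over sequence pairs of identities / jointly occupied columns.

    Pairs with no jointly occupied column are excluded with a warning.
    """
    if aln.S < 2:
        raise ValueError("average pairwise identity needs at least 2 sequences")
    codes = aln.codes()
    occupied = codes != GAP_CODE
    idents = []
    skipped = 0
    for a in range(aln.S):
        for b in range(a + 1, aln.S):
            both = occupied[a] & occupied[b]
            n = int(both.sum())
            if n == 0:
                skipped += 1
                continue
            idents.append(float((codes[a][both] == codes[b][both]).sum()) / n)
    if skipped:
        warnings.warn(f"{skipped} sequence pair(s) share no occupied column; excluded",
                      stacklevel=2)
    if not idents:
        raise ValueError("no sequence pair shares an occupied column")
    return float(np.mean(idents))


@dataclass
class ColumnProfile:
    """Per-column residue counts and occupancy for one alignment.

    ``counts`` is (L, 4) over A,C,G,U; ``gaps`` is (L,); ``occupancy`` is the
    fraction of rows carrying a residue. Joint pair counts are computed on
    demand with :func:`pair_counts` (rows gapped at either column excluded).
    """

    counts: np.ndarray
    gaps: np.ndarray
    occupancy: np.ndarray
    S: int

    def __post_init__(self) -> None:
        total = self.counts.sum(axis=1) + self.gaps
        if not np.all(total == self.S):
            raise ValueError("column counts do not sum to the number of sequences")


def column_profiles(aln: Alignment) -> ColumnProfile:
    codes = aln.codes()
    counts = np.stack([(codes == k).sum(axis=0) for k in range(4)], axis=1)
    gaps = (codes == GAP_CODE).sum(axis=0)
    return ColumnProfile(counts=counts, gaps=gaps,
                         occupancy=1.0 - gaps / aln.S, S=aln.S)


def pair_counts(aln: Alignment, i: int, j: int) -> np.ndarray:
    """4x4 joint residue counts at columns (i, j) over jointly occupied rows."""
    codes = aln.codes()
    ci, cj = codes[:, i], codes[:, j]
    keep = (ci != GAP_CODE) & (cj != GAP_CODE)
    out = np.zeros((4, 4), dtype=np.int64)
    np.add.at(out, (ci[keep], cj[keep]), 1)
    return out


def alignment_summary(aln: Alignment) -> dict:
    """JSON-ready summary used by the CLI."""
    prof = column_profiles(aln)
    summary = {
        "n_sequences": aln.S,
        "n_columns": aln.L,
        "mean_occupancy": float(prof.occupancy.mean()),
        "n_structure_pairs": len(aln.structure.pairs) if aln.structure else 0,
    }
    if aln.S >= 2:
        summary["average_pairwise_identity"] = average_pairwise_identity(aln)
    return summary


def summary_json(aln: Alignment) -> str:
    return json.dumps(alignment_summary(aln), indent=2)
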