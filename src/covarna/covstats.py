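"""Column-pair covariation statistics.

Two statistics are supported for significance testing: mutual information
(MI, in bits, computed on joint residue frequencies) and the G-test
(natural-log likelihood-ratio statistic on observed counts). On gap-free
pairs the two are related by ``G = 2 * N * ln(2) * MI``; the G-test carries
an extra dependence on occupancy, which MI deliberately lacks.

The RAF score (and its stacking-averaged variant) mixes covariation with
conservation and structure compatibility. It is provided for diagnostics
only and is refused by the significance pipeline.

Rows gapped at either column of a pair are excluded from that pair's
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .msa_io import Alignment, GAP_CODE

__all__ = [
    "PairScore",
    "ScoreMatrix",
    "mi",
    "gtest",
    "mi_from_counts",
    "gtest_from_counts",
    "joint_counts",
    "all_pair_indices",
    "score_alignment",
    "raf",
    "apc",
    "SECIS_FIRST_PAIR_EMISSION",
    "SIGNIFICANCE_STATS",
]

#: ln(2): G-test (nats) vs MI (bits) conversion, G = 2 N LN2 MI on gap-free pairs
LN2 = float(np.log(2.0))

#: statistics admissible for E-value significance testing
SIGNIFICANCE_STATS = ("gtest", "mi")

# Pair emission probabilities (rows A,C,G,U x cols A,C,G,U) of the first
# consensus base pair (a G:C) of the Rfam SECIS_1 covariance model
# (RF00031), before pseudocounts. Used as a worked example: the 16 entries
# sum to 1 and give a hand-checkable MI.
SECIS_FIRST_PAIR_EMISSION = np.array([
    [0.000, 0.000, 0.000, 0.047],
    [0.000, 0.035, 0.201, 0.000],
    [0.000, 0.348, 0.000, 0.123],
    [0.231, 0.015, 0.000, 0.000],
])

_CANONICAL = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}  # AU UA CG GC GU UG


@dataclass(frozen=True)
class PairScore:
    i: int
    j: int
    statistic: str
    raw: float
    corrected: Optional[float] = None

    def __post_init__(self) -> None:
        if self.i > self.j:
            object.__setattr__(self, "i", self.j)
            object.__setattr__(self, "j", self.i)


def mi(joint: np.ndarray, base: float = 2.0) -> float:
    """Mutual information of a 4x4 joint distribution (bits by default).

    ``joint`` must sum to 1; marginals are taken from the joint. The
    convention 0*log(0) = 0 applies.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.shape != (4, 4):
        raise ValueError("joint distribution must be 4x4")
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty joint distribution: MI undefined")
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"joint distribution sums to {total}, not 1")
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    mask = joint > 0
    ratio = joint[mask] / (np.outer(pi, pj)[mask])
    return float(np.sum(joint[mask] * np.log(ratio)) / np.log(base))


def gtest(counts: np.ndarray) -> float:
    """G statistic (natural log) of a 4x4 table of observed pair counts.

    Zero total support returns 0 (the zero-support convention).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4, 4):
        raise ValueError("counts must be 4x4")
    return float(gtest_from_counts(counts[None, :, :])[0])


def mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized MI (bits) from (P, 4, 4) count tables; zero support -> 0."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(1, 2))
    safe_n = np.where(n > 0, n, 1.0)
    joint = counts / safe_n[:, None, None]
    pi = joint.sum(axis=2)
    pj = joint.sum(axis=1)
    denom = pi[:, :, None] * pj[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / denom)
    terms[~np.isfinite(terms)] = 0.0
    out = terms.sum(axis=(1, 2))
    out[n == 0] = 0.0
    return np.maximum(out, 0.0)


def gtest_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized G-test (nats) from (P, 4, 4) count tables."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(1, 2))
    ri = counts.sum(axis=2)
    cj = counts.sum(axis=1)
    expected = ri[:, :, None] * cj[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts * n[:, None, None] / expected)
    terms[~np.isfinite(terms)] = 0.0
    out = 2.0 * terms.sum(axis=(1, 2))
    out[n == 0] = 0.0
    return np.maximum(out, 0.0)


def all_pair_indices(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (ii, jj) for all column pairs i < j."""
    ii, jj = np.triu_indices(L, k=1)
    return ii, jj


def joint_counts(codes: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """Joint 4x4 residue counts for pair list (ii, jj); gapped rows excluded.

    ``codes`` is the (S, L) int8 matrix from :meth:`Alignment.codes`.
    Returns (P, 4, 4) float64.
    """
    onehot = np.zeros((codes.shape[0], codes.shape[1], 4), dtype=np.float64)
    for k in range(4):
        onehot[:, :, k] = codes == k
    return np.einsum("spa,spb->pab", onehot[:, ii, :], onehot[:, jj, :], optimize=True)


@dataclass
class ScoreMatrix:
    """All pair scores for one alignment and statistic.

    ``ii``/``jj`` index the scored pairs (i < j). ``corrected`` holds the
    APC-corrected values and is None until :func:`apc` is applied (APC needs
    the complete pair set).
    """

    statistic: str
    L: int
    ii: np.ndarray
    jj: np.ndarray
    raw: np.ndarray
    corrected: Optional[np.ndarray] = None
    complete: bool = True

    def values(self, use_apc: bool = True) -> np.ndarray:
        if use_apc:
            if self.corrected is None:
                raise ValueError("APC correction has not been applied")
            return self.corrected
        return self.raw

    def as_square(self, use_apc: bool = False) -> np.ndarray:
        vals = self.values(True) if use_apc else self.raw
        m = np.zeros((self.L, self.L))
        m[self.ii, self.jj] = vals
        m[self.jj, self.ii] = vals
        return m


def score_alignment(aln_or_codes, statistic: str = "gtest",
                    pairs: Optional[tuple[np.ndarray, np.ndarray]] = None,
                    use_apc: bool = True) -> ScoreMatrix:
    """Score column pairs of an alignment with MI or the G-test.

    ``pairs`` restricts scoring to an explicit (ii, jj) pair list, in which
    case APC is unavailable (it needs the complete matrix) and is skipped.
    """
    if statistic not in SIGNIFICANCE_STATS:
        raise ValueError(f"unknown covariation statistic {statistic!r}")
    codes = aln_or_codes.codes() if isinstance(aln_or_codes, Alignment) else aln_or_codes
    L = codes.shape[1]
    complete = pairs is None
    ii, jj = all_pair_indices(L) if pairs is None else pairs
    counts = joint_counts(codes, ii, jj)
    raw = gtest_from_counts(counts) if statistic == "gtest" else mi_from_counts(counts)
    sm = ScoreMatrix(statistic=statistic, L=L, ii=np.asarray(ii), jj=np.asarray(jj),
                     raw=raw, complete=complete)
    if use_apc and complete and L >= 3:
        apc(sm)
    return sm


def apc(sm: ScoreMatrix) -> ScoreMatrix:
    """Apply the average product correction in place.

    corrected_ij = raw_ij - mean_i * mean_j / grand_mean, with row and grand
    means taken over off-diagonal entries. A zero grand mean skips the
    correction (corrected = raw).
    """
    if not sm.complete:
        raise ValueError("APC requires the complete pair matrix")
    L = sm.L
    m = np.zeros((L, L))
    m[sm.ii, sm.jj] = sm.raw
    m[sm.jj, sm.ii] = sm.raw
    row_mean = m.sum(axis=1) / (L - 1)
    grand = m.sum() / (L * (L - 1))
    if grand == 0:
        sm.corrected = sm.raw.copy()
        return sm
    sm.corrected = sm.raw - row_mean[sm.ii] * row_mean[sm.jj] / grand
    return sm


def raf(aln: Alignment, i: int, j: int, stacking: bool = False) -> float:
    """RAF covariation/conservation score for columns (i, j) — diagnostic only.

    Pairwise change term: +2 for a double and +1 for a half change between
    two sequences whose (i, j) residues both form canonical pairs
    (Watson-Crick or G:U), normalized by the number of sequence pairs.
    Penalty term: -1 per sequence whose (i, j) is non-canonical or contains
    a gap, normalized by the number of sequences (i.e. the invalid
    fraction, the RNAalifold convention). ``stacking`` averages with the
    inner neighbor pair.

    Because the penalty rewards columns where every sequence keeps a
    canonical pair, this score mixes conservation into covariation and
    must never be fed to the phylogenetic-null significance test.
    """
    if stacking:
        scores = [raf(aln, i, j, stacking=False)]
        if i + 1 < j - 1:
            scores.append(raf(aln, i + 1, j - 1, stacking=False))
        return float(np.mean(scores))
    codes = aln.codes()
    a = codes[:, i]
    b = codes[:, j]
    S = aln.S
    valid = np.array([(int(x), int(y)) in _CANONICAL for x, y in zip(a, b)])
    penalties = -float((~valid).sum())
    changes = 0.0
    idx = np.nonzero(valid)[0]
    for u in range(len(idx)):
        for v in range(u + 1, len(idx)):
            s, t = idx[u], idx[v]
            diff = int(a[s] != a[t]) + int(b[s] != b[t])
            if diff == 2:
                changes += 2.0
            elif diff == 1:
                changes += 1.0
    n_pairs = S * (S - 1) / 2
    return float(changes / n_pairs + penalties / S)
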