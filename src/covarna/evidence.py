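"""Significance, covariation power, and the structure-evidence call.

E-values are empirical: the covariation score of every column pair of the
input alignment is compared against the pooled pair scores of an ensemble
of phylogenetic null alignments. E(s) is the expected number of null pairs
per null alignment scoring >= s; scores beyond the pooled maximum are
extrapolated with a maximum-likelihood exponential tail fitted to the top
decile of null scores. A pair significantly covaries when E < 0.05 (the
default threshold).

Power is the probability that a pair would be detected as significantly
covarying given its substitution count, fitted as an isotonic (monotone
non-decreasing) curve on labelled training pairs from alignments with
trusted structures, in either single-substitution (sum of per-column
counts) or double-substitution (branches substituting at both columns)
mode.

The alignment-level call combines observed significant pairs with the
expected covarying count: STRUCTURAL needs at least three significant
pairs; with none, low expected power means CANNOT_TELL and high
double-substitution power means NEGATIVE; high single- but low double-subs
power flags an alignment inconsistent with the proposed pairing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .msa_io import Alignment, ConsensusStructure
from .nullgen import NullAlignment, null_ensemble
from .phylo import (PhyloTree, SubstitutionMap, build_tree, count_substitutions,
                    fitch_sample, pair_substitution_counts)
from .covstats import SIGNIFICANCE_STATS, ScoreMatrix, score_alignment

__all__ = [
    "NullDistribution",
    "PairEvidence",
    "PowerCurve",
    "StructureCall",
    "build_null_distribution",
    "evalue",
    "pair_evidence",
    "significant_pairs",
    "fit_power_curve",
    "default_power_curve",
    "expected_covarying",
    "classify",
    "analyze",
    "AnalysisResult",
]

DEFAULT_EVALUE_THRESHOLD = 0.05
#: minimum ratio of pooled null scores to scored alignment pairs
MIN_NULL_OVERSAMPLING = 10

_CLASSES = ("STRUCTURAL", "NEGATIVE", "CANNOT_TELL", "INCONSISTENT_POWER", "INCONCLUSIVE")


def _check_statistic(statistic: str) -> None:
    if statistic.lower().startswith("raf"):
        raise ValueError(
            "RAF/RAFS mix covariation with conservation and structure "
            "compatibility; the phylogenetic null does not preserve "
            "conservation, so RAF significance would be artifactual. "
            "RAF is available from covstats.raf for diagnostics only."
        )
    if statistic not in SIGNIFICANCE_STATS:
        raise ValueError(f"unknown covariation statistic {statistic!r}")


@dataclass
class NullDistribution:
    """Pooled null pair scores with an exponential upper tail."""

    statistic: str
    use_apc: bool
    scores: np.ndarray  # sorted ascending
    n_nulls: int
    pairs_per_alignment: float
    tail_loc: float = field(default=float("nan"))
    tail_rate: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if math.isnan(self.tail_loc) and self.scores.size:
            # ML exponential on exceedances over the 97.5th percentile
            # (peaks-over-threshold; at least 50 exceedances kept)
            n_exc = max(50, int(round(0.025 * self.scores.size)))
            n_exc = min(n_exc, self.scores.size)
            self.tail_loc = float(self.scores[-n_exc])
            exceed = self.scores[self.scores >= self.tail_loc] - self.tail_loc
            mean_exc = float(exceed.mean()) if exceed.size else 0.0
            self.tail_rate = 1.0 / mean_exc if mean_exc > 0 else float("inf")

    def survival_count(self, score: float) -> int:
        return int(self.scores.size - np.searchsorted(self.scores, score, side="left"))


def build_null_distribution(nulls: Sequence[NullAlignment], statistic: str = "gtest",
                            use_apc: bool = True,
                            pairs: Optional[tuple[np.ndarray, np.ndarray]] = None,
                            ) -> NullDistribution:
    _check_statistic(statistic)
    if not nulls:
        raise ValueError("at least one null alignment is required")
    pooled = []
    n_pairs = None
    for null in nulls:
        sm = score_alignment(null.alignment, statistic=statistic, pairs=pairs,
                             use_apc=use_apc)
        vals = sm.values(use_apc and sm.corrected is not None)
        pooled.append(vals)
        n_pairs = vals.size
    return NullDistribution(statistic=statistic, use_apc=use_apc,
                            scores=np.concatenate(pooled), n_nulls=len(nulls),
                            pairs_per_alignment=float(n_pairs))


def evalue(score: float, null: NullDistribution) -> float:
    """Expected null pairs per alignment scoring >= ``score``.

    Empirical beyond-count divided by the number of null alignments; for
    scores above every pooled null score, the exponential tail extrapolates
    (capped at 1/M to stay monotone with the empirical region).
    """
    k = null.survival_count(score)
    if k >= 1:
        return k / null.n_nulls
    if not math.isfinite(null.tail_rate):
        return 1.0 / null.n_nulls
    n_exc = null.survival_count(null.tail_loc)
    tail = (n_exc / null.n_nulls) * math.exp(-null.tail_rate * (score - null.tail_loc))
    return float(min(1.0 / null.n_nulls, tail))


@dataclass
class PairEvidence:
    """Per-pair covariation evidence."""

    i: int
    j: int
    statistic: str
    raw: float
    score: float  # APC-corrected when APC is in use, else raw
    evalue: float
    significant: bool
    subs_single: Optional[int] = None
    subs_double: Optional[int] = None
    power_single: Optional[float] = None
    power_double: Optional[float] = None

    def to_row(self) -> dict:
        return {
            "i": self.i + 1,  # 1-based user-facing coordinates
            "j": self.j + 1,
            "statistic": self.statistic,
            "raw": self.raw,
            "score": self.score,
            "evalue": self.evalue,
            "significant": self.significant,
            "subs_single": self.subs_single,
            "subs_double": self.subs_double,
            "power_single": self.power_single,
            "power_double": self.power_double,
        }


def pair_evidence(aln: Alignment, nulls: Sequence[NullAlignment],
                  statistic: str = "gtest",
                  threshold: float = DEFAULT_EVALUE_THRESHOLD,
                  use_apc: bool = True,
                  pairs: Optional[tuple[np.ndarray, np.ndarray]] = None,
                  ) -> list[PairEvidence]:
    """Evidence for every scored pair, sorted by (E-value, i, j)."""
    _check_statistic(statistic)
    sm = score_alignment(aln, statistic=statistic, pairs=pairs, use_apc=use_apc)
    apc_active = use_apc and sm.corrected is not None
    null = build_null_distribution(nulls, statistic=statistic, use_apc=apc_active,
                                   pairs=pairs)
    values = sm.values(apc_active)
    out = []
    for i, j, raw, val in zip(sm.ii, sm.jj, sm.raw, values):
        e = evalue(float(val), null)
        out.append(PairEvidence(i=int(i), j=int(j), statistic=statistic,
                                raw=float(raw), score=float(val), evalue=e,
                                significant=e < threshold))
    out.sort(key=lambda p: (p.evalue, p.i, p.j))
    return out


def significant_pairs(aln: Alignment, nulls: Sequence[NullAlignment],
                      statistic: str = "gtest",
                      threshold: float = DEFAULT_EVALUE_THRESHOLD,
                      use_apc: bool = True,
                      pairs: Optional[tuple[np.ndarray, np.ndarray]] = None,
                      ) -> list[PairEvidence]:
    """The significantly covarying pairs (E < threshold), best first."""
    return [p for p in pair_evidence(aln, nulls, statistic, threshold, use_apc, pairs)
            if p.significant]


@dataclass
class PowerCurve:
    """Monotone map from substitution count to detection probability.

    ``mode`` is "single" or "double" (which substitution count the x-axis
    uses); ``source`` records the calibration provenance. The curve is 0 at
    0 substitutions and piecewise-linear between fitted levels.
    """

    xs: np.ndarray
    ys: np.ndarray
    mode: str = "single"
    source: str = "user"

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.clip(np.asarray(self.ys, dtype=float), 0.0, 1.0)
        if np.any(np.diff(self.xs) <= 0):
            raise ValueError("power-curve x values must be strictly increasing")
        if np.any(np.diff(self.ys) < -1e-12):
            raise ValueError("power-curve values must be non-decreasing")
        if self.xs[0] > 0:
            self.xs = np.concatenate([[0.0], self.xs])
            self.ys = np.concatenate([[0.0], self.ys])
        self.ys[self.xs == 0] = 0.0

    def __call__(self, subs) -> np.ndarray | float:
        val = np.interp(subs, self.xs, self.ys)
        return float(val) if np.isscalar(subs) else val


def fit_power_curve(training: Iterable[tuple[int, bool]], mode: str = "single",
                    source: str = "user") -> PowerCurve:
    """Isotonic fit of detection probability vs substitution count.

    ``training`` holds (substitution count, was_significant) pairs for
    proposed base pairs of trusted structural alignments.
    """
    data = [(int(x), bool(y)) for x, y in training]
    if not data:
        raise ValueError("empty power training set")
    xs = np.array([x for x, _ in data], dtype=float)
    ys = np.array([1.0 if y else 0.0 for _, y in data])
    if np.unique(xs).size < 2:
        raise ValueError("degenerate power training set: a single substitution level")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                             out_of_bounds="clip")
    iso.fit(xs, ys)
    grid = np.unique(xs)
    return PowerCurve(xs=grid, ys=iso.predict(grid), mode=mode, source=source)


# Default power curves, produced by synth.calibrate_power_curves(seed=0,
# replicates=4): random binary trees (S=40, L=80, 10 constrained pairs,
# branch lengths 0.05-0.7), Watson-Crick-preserving pair kernel, G-test +
# APC vs 20 gap-preserving nulls, significance at E < 0.05. Users analysing
# curated alignments should recalibrate on trusted structures.
_DEFAULT_POWER_SINGLE = (
    (0, 0.0), (7, 0.0), (8, 0.059), (9, 0.059), (10, 0.222), (11, 0.444),
    (12, 0.5), (14, 0.6), (16, 0.759), (19, 0.759), (20, 0.87), (25, 0.87),
    (26, 0.929), (27, 0.975), (34, 0.975), (35, 0.982), (38, 0.982),
    (39, 1.0),
)
_DEFAULT_POWER_DOUBLE = (
    (0, 0.0), (1, 0.091), (2, 0.3), (3, 0.364), (4, 0.475), (5, 0.82),
    (6, 0.876), (7, 0.876), (8, 0.939), (9, 0.967), (10, 1.0),
)


def default_power_curve(mode: str = "single") -> PowerCurve:
    """The shipped synthetic-calibration power curve."""
    table = _DEFAULT_POWER_SINGLE if mode == "single" else _DEFAULT_POWER_DOUBLE
    xs, ys = zip(*table)
    return PowerCurve(xs=np.array(xs, float), ys=np.array(ys, float),
                      mode=mode, source="synthetic-default")


def expected_covarying(structure: ConsensusStructure, smap: SubstitutionMap,
                       curve: PowerCurve) -> float:
    """Sum of per-pair power over the proposed structure pairs."""
    total = 0.0
    for i, j in sorted(structure.pairs):
        single, double = pair_substitution_counts(smap, i, j)
        total += curve(single if curve.mode == "single" else double)
    return float(total)


@dataclass
class StructureCall:
    classification: str
    observed: int
    expected_single: float
    expected_double: float

    def __post_init__(self) -> None:
        if self.classification not in _CLASSES:
            raise ValueError(f"unknown classification {self.classification}")


def classify(observed: int, expected_single: float,
             expected_double: float) -> StructureCall:
    """Four-way structure-evidence classification of one alignment.

    STRUCTURAL: >= 3 significant pairs. Without covariation: CANNOT_TELL
    when expected covarying pairs <= 5; NEGATIVE when the double-subs
    expectation >= 8; INCONSISTENT_POWER when single-subs power is high
    (>= 8) but double-subs power low (<= 5); INCONCLUSIVE otherwise.
    """
    if observed < 0 or expected_single < 0 or expected_double < 0:
        raise ValueError("counts must be non-negative")
    if observed >= 3:
        label = "STRUCTURAL"
    elif expected_single <= 5:
        label = "CANNOT_TELL"
    elif expected_double >= 8:
        label = "NEGATIVE"
    elif expected_single >= 8 and expected_double <= 5:
        label = "INCONSISTENT_POWER"
    else:
        label = "INCONCLUSIVE"
    return StructureCall(classification=label, observed=observed,
                         expected_single=expected_single,
                         expected_double=expected_double)


@dataclass
class AnalysisResult:
    evidences: list[PairEvidence]
    call: Optional[StructureCall]
    n_nulls: int
    statistic: str
    threshold: float

    @property
    def significant(self) -> list[PairEvidence]:
        return [p for p in self.evidences if p.significant]

    def to_json(self) -> str:
        payload = {
            "statistic": self.statistic,
            "evalue_threshold": self.threshold,
            "n_nulls": self.n_nulls,
            "n_significant": len(self.significant),
            "call": None if self.call is None else {
                "classification": self.call.classification,
                "observed": self.call.observed,
                "expected_single": self.call.expected_single,
                "expected_double": self.call.expected_double,
            },
        }
        return json.dumps(payload, indent=2)


def analyze(aln: Alignment, n_nulls: int = 20, statistic: str = "gtest",
            gap_preserving: bool = True,
            threshold: float = DEFAULT_EVALUE_THRESHOLD,
            seed: Optional[int] = None, tree: Optional[PhyloTree] = None,
            use_apc: bool = True,
            power_single: Optional[PowerCurve] = None,
            power_double: Optional[PowerCurve] = None,
            min_pair_separation: int = 4) -> AnalysisResult:
    """Full covariation/power analysis of one alignment.

    Pairs closer than ``min_pair_separation`` are scored and reported but
    never counted in the structure-evidence summary (adjacent covariation
    is a protein-coding signal, not an RNA base-pairing one). When the
    alignment carries a consensus structure, the structure call combines
    observed significant structure pairs with expected covarying counts
    under the single- and double-substitution power curves.
    """
    _check_statistic(statistic)
    if tree is None:
        tree = build_tree(aln)
    if n_nulls * 1.0 < MIN_NULL_OVERSAMPLING:
        n_nulls = MIN_NULL_OVERSAMPLING
    rng = np.random.SeedSequence(seed)
    null_seed, fitch_seed = [int(s.generate_state(1)[0]) for s in rng.spawn(2)]
    nulls = null_ensemble(aln, tree, n_nulls=n_nulls, seed=null_seed,
                          gap_preserving=gap_preserving)
    evidences = pair_evidence(aln, nulls, statistic=statistic, threshold=threshold,
                              use_apc=use_apc)
    smap = count_substitutions(fitch_sample(aln, tree, fitch_seed))
    for ev in evidences:
        single, double = pair_substitution_counts(smap, ev.i, ev.j)
        ev.subs_single, ev.subs_double = single, double
    curve_s = power_single or default_power_curve("single")
    curve_d = power_double or default_power_curve("double")
    for ev in evidences:
        ev.power_single = float(curve_s(ev.subs_single))
        ev.power_double = float(curve_d(ev.subs_double))
    call = None
    if aln.structure is not None and aln.structure.pairs:
        struct_pairs = {(i, j) for i, j in aln.structure.pairs
                        if j - i >= min_pair_separation}
        observed = sum(1 for p in evidences
                       if p.significant and (p.i, p.j) in struct_pairs)
        exp_s = expected_covarying(aln.structure, smap, curve_s)
        exp_d = expected_covarying(aln.structure, smap, curve_d)
        call = classify(observed, exp_s, exp_d)
    return AnalysisResult(evidences=evidences, call=call, n_nulls=n_nulls,
                          statistic=statistic, threshold=threshold)


def raf_artifact_diagnostic(aln: Alignment, nulls: Sequence[NullAlignment],
                            pairs: Iterable[tuple[int, int]],
                            ) -> tuple[float, float, float]:
    """Empirical p of the mean RAF over proposed pairs vs null alignments.

    Demonstrates why RAF must not be used for significance: because the
    nulls destroy per-column conservation, a helix of perfectly conserved
    canonical pairs with zero covariation outranks nearly every null and
    would look "significant" under a conservation-mixing score.
    Returns (source mean RAF, null mean RAF, empirical p).
    """
    from .covstats import raf

    pair_list = sorted(pairs)
    if not pair_list:
        raise ValueError("no pairs supplied")
    src = float(np.mean([raf(aln, i, j) for i, j in pair_list]))
    null_means = [float(np.mean([raf(n.alignment, i, j) for i, j in pair_list]))
                  for n in nulls]
    p = (1 + sum(1 for v in null_means if v >= src)) / (1 + len(null_means))
    return src, float(np.mean(null_means)), float(p)
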