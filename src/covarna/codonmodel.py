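"""Protein-codon evolution and expected within-codon covariation.

Covariation between positions of the same codon in protein-coding
alignments arises from the genetic code: an ancestral amino acid ``a``
evolves into ``b`` with probability P(b|a,t) under an amino-acid
substitution process, and ``b`` is then encoded according to stationary
per-amino-acid codon biases,

    P(c1 c2 c3 | a, t) = sum_b P(c1 c2 c3 | b) P(b | a, t).

The expected within-codon covariation is the mutual information of the
two-position marginals of that codon distribution. Stop codons are outside
the state space (BLOSUM-style models have no sense/stop exchange), indels
are ignored, and sequences descend independently from the ancestor (star
topology).

The amino-acid process is a reversible rate matrix derived from BLOSUM62:
joint (target) frequencies are recovered from the integer log-odds scores
by fixed-point iteration, the conditional matrix is carried to a generator
by a matrix logarithm (negative off-diagonal entries zeroed, diagonal
reset), and the generator is normalized to one expected substitution per
site at t = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy.linalg import expm, logm

from .msa_io import Alignment
from .covstats import mi

__all__ = [
    "AMINO_ACIDS",
    "GeneticCode",
    "CodonBias",
    "AminoAcidModel",
    "CodonDistribution",
    "standard_genetic_code",
    "uniform_codon_bias",
    "codon_bias_from_counts",
    "build_amino_model",
    "codon_distribution",
    "within_codon_mi",
    "mi_trajectory",
    "simulate_exon_alignment",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NT_INDEX = {c: i for i, c in enumerate("ACGU")}

PAIR_LABELS = {"c1c2": (0, 1), "c1c3": (0, 2), "c2c3": (1, 2)}


@dataclass(frozen=True)
class GeneticCode:
    """Sense codons of a genetic code (RNA alphabet, stops excluded)."""

    codon_to_aa: dict[str, str]

    @property
    def aa_to_codons(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {a: [] for a in AMINO_ACIDS}
        for codon, aa in sorted(self.codon_to_aa.items()):
            out[aa].append(codon)
        return {a: tuple(cs) for a, cs in out.items()}

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def six_box_amino_acids(self) -> tuple[str, ...]:
        return tuple(a for a, cs in self.aa_to_codons.items() if len(cs) == 6)


def standard_genetic_code() -> GeneticCode:
    table = CodonTable.unambiguous_rna_by_id[1]
    return GeneticCode(codon_to_aa=dict(table.forward_table))


@dataclass(frozen=True)
class CodonBias:
    """P(codon | amino acid) over each amino acid's synonymous codons."""

    probs: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        code = standard_genetic_code()
        syn = code.aa_to_codons
        for aa, dist in self.probs.items():
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"codon bias for {aa} sums to {total}, not 1")
            extra = set(dist) - set(syn[aa])
            if extra:
                raise ValueError(f"codon bias for {aa} puts mass on {sorted(extra)}")

    def vector(self, aa: str, codons: tuple[str, ...]) -> np.ndarray:
        dist = self.probs[aa]
        return np.array([dist.get(c, 0.0) for c in codons])


def uniform_codon_bias() -> CodonBias:
    code = standard_genetic_code()
    probs = {aa: {c: 1.0 / len(cs) for c in cs}
             for aa, cs in code.aa_to_codons.items()}
    return CodonBias(probs=probs)


def codon_bias_from_counts(path: str | Path) -> CodonBias:
    """Codon bias from a tab-separated ``codon<TAB>count`` table.

    Counts are normalized within each amino acid; DNA codons (T) are
    accepted. Codons absent from the table get zero mass; amino acids with
    no counted codon fall back to uniform.
    """
    code = standard_genetic_code()
    counts: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, value = line.split("\t")[:2]
        codon = codon.upper().replace("T", "U")
        if codon not in code.codon_to_aa:
            continue  # stop or malformed codon
        counts[codon] = counts.get(codon, 0.0) + float(value)
    probs: dict[str, dict[str, float]] = {}
    for aa, codons in code.aa_to_codons.items():
        total = sum(counts.get(c, 0.0) for c in codons)
        if total > 0:
            probs[aa] = {c: counts.get(c, 0.0) / total for c in codons}
        else:
            probs[aa] = {c: 1.0 / len(codons) for c in codons}
    return CodonBias(probs=probs)


@dataclass
class AminoAcidModel:
    """Reversible amino-acid substitution process.

    ``rate`` is a 20x20 generator with stationary distribution ``pi``,
    normalized so the expected number of substitutions per site at t = 1
    is one: sum_a pi_a * (-rate_aa) = 1.
    """

    rate: np.ndarray
    pi: np.ndarray
    alphabet: str = AMINO_ACIDS

    def transition(self, t: float) -> np.ndarray:
        """P(b | a, t); rows indexed by ancestral amino acid a."""
        if t < 0:
            raise ValueError("divergence time must be non-negative")
        if t == 0:
            return np.eye(len(self.alphabet))
        return expm(self.rate * t)

    def expected_substitutions(self, t: float = 1.0) -> float:
        return float(-np.sum(self.pi * np.diag(self.rate)) * t)


def _blosum_joint() -> tuple[np.ndarray, np.ndarray]:
    """Recover BLOSUM62 joint (target) frequencies from the score matrix.

    BLOSUM scores are s = round(2 * log2(q_ab / (p_a p_b))), so
    q = p p^T * M / Z with M = 2^(s/2). Requiring the marginals of q to
    equal p gives the linear system M u = 1 with u proportional to p; the
    solve reproduces the published background frequencies to rounding
    accuracy.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    scores = np.empty((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = blosum[a, b]
    weight = np.power(2.0, scores / 2.0)
    u = np.linalg.solve(weight, np.ones(n))
    if np.any(u <= 0):
        raise ValueError("BLOSUM62 frequency recovery produced negative mass")
    p = u / u.sum()
    q = np.outer(p, p) * weight
    q /= q.sum()
    return q, p


def build_amino_model() -> AminoAcidModel:
    """Rate matrix derived from BLOSUM62, one substitution per site at t=1."""
    joint, p = _blosum_joint()
    conditional = joint / p[:, None]
    gen = logm(conditional)
    gen = np.real(gen)
    off = gen - np.diag(np.diag(gen))
    off[off < 0] = 0.0  # project onto valid generators
    rate = off - np.diag(off.sum(axis=1))
    # stationary distribution of the projected generator
    w, v = np.linalg.eig(rate.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    scale = -np.sum(pi * np.diag(rate))
    rate = rate / scale
    return AminoAcidModel(rate=rate, pi=pi)


@lru_cache(maxsize=1)
def _default_model() -> AminoAcidModel:
    return build_amino_model()


@dataclass
class CodonDistribution:
    """P(codon | ancestral amino acid, t) over the 61 sense codons."""

    codons: tuple[str, ...]
    probs: np.ndarray
    amino_acid: str
    t: float

    def __post_init__(self) -> None:
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-9):
            raise ValueError("codon distribution does not sum to 1")

    def marginal_pair(self, pair: str) -> np.ndarray:
        """4x4 joint nucleotide distribution of two codon positions."""
        if pair not in PAIR_LABELS:
            raise ValueError(f"unknown codon position pair {pair!r}; "
                             f"expected one of {sorted(PAIR_LABELS)}")
        u, v = PAIR_LABELS[pair]
        out = np.zeros((4, 4))
        for codon, prob in zip(self.codons, self.probs):
            out[_NT_INDEX[codon[u]], _NT_INDEX[codon[v]]] += prob
        return out


def _codon_matrix(bias: CodonBias, code: GeneticCode) -> tuple[tuple[str, ...], np.ndarray]:
    codons = code.codons
    idx = {c: k for k, c in enumerate(codons)}
    mat = np.zeros((len(AMINO_ACIDS), len(codons)))
    for aa, cs in code.aa_to_codons.items():
        for c in cs:
            mat[_AA_INDEX[aa], idx[c]] = bias.probs[aa].get(c, 0.0)
    return codons, mat


def codon_distribution(aa: str, t: float, bias: Optional[CodonBias] = None,
                       model: Optional[AminoAcidModel] = None) -> CodonDistribution:
    if aa not in _AA_INDEX:
        raise ValueError(f"unknown amino acid {aa!r}")
    if t < 0:
        raise ValueError("divergence time must be non-negative")
    bias = bias or uniform_codon_bias()
    model = model or _default_model()
    code = standard_genetic_code()
    codons, emission = _codon_matrix(bias, code)
    trans = model.transition(t)[_AA_INDEX[aa]]
    probs = trans @ emission
    probs = np.maximum(probs, 0.0)
    probs /= probs.sum()
    return CodonDistribution(codons=codons, probs=probs, amino_acid=aa, t=t)


def within_codon_mi(aa: str, t: float, pair: str,
                    bias: Optional[CodonBias] = None,
                    model: Optional[AminoAcidModel] = None) -> float:
    """Expected within-codon covariation (MI, bits) of one position pair."""
    dist = codon_distribution(aa, t, bias, model)
    return mi(dist.marginal_pair(pair))


def mi_trajectory(aa: str, pair: str, t_grid, bias: Optional[CodonBias] = None,
                  model: Optional[AminoAcidModel] = None) -> np.ndarray:
    """MI along a divergence grid (one value per t)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D grid")
    if np.any(t_grid < 0) or np.any(np.diff(t_grid) <= 0) and t_grid.size > 1:
        raise ValueError("t_grid must be positive and increasing")
    bias = bias or uniform_codon_bias()
    model = model or _default_model()
    return np.array([within_codon_mi(aa, float(t), pair, bias, model)
                     for t in t_grid])


def total_within_codon_mi(aa: str, t: float, bias: Optional[CodonBias] = None,
                          model: Optional[AminoAcidModel] = None) -> float:
    """Sum of the three within-codon pair MIs for one amino acid."""
    bias = bias or uniform_codon_bias()
    model = model or _default_model()
    dist = codon_distribution(aa, t, bias, model)
    return float(sum(mi(dist.marginal_pair(p)) for p in PAIR_LABELS))


def simulate_exon_alignment(ancestral_protein: str, t: float, n_sequences: int,
                            bias: Optional[CodonBias] = None,
                            model: Optional[AminoAcidModel] = None,
                            seed: Optional[int | np.random.Generator] = None,
                            ) -> Alignment:
    """Star-topology exon alignment: codons drawn independently per sequence.

    Returns a gap-free RNA alignment of length 3 * len(ancestral_protein).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bias = bias or uniform_codon_bias()
    model = model or _default_model()
    dists = [codon_distribution(aa, t, bias, model) for aa in ancestral_protein]
    rows = []
    for _ in range(n_sequences):
        seq = []
        for dist in dists:
            k = rng.choice(len(dist.codons), p=dist.probs)
            seq.append(dist.codons[k])
        rows.append("".join(seq))
    names = [f"seq{k + 1}" for k in range(n_sequences)]
    return Alignment(names=names, rows=rows)
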