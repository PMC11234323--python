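import numpy as np
import pytest

from covarna.msa_io import Alignment
from covarna.synth import SimConfig, simulate_structural_alignment


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment(
        names=["a", "b", "c"],
        rows=["ACGUACGU", "ACGUACGG", "ACGU-CGU"],
    )


@pytest.fixture
def random_alignment() -> Alignment:
    """10 x 20 gapless alignment evolved on a random tree."""
    cfg = SimConfig(S=10, L=20, branch_length=0.4, seed=11)
    aln, _ = simulate_structural_alignment(cfg)
    return aln


@pytest.fixture
def gappy_alignment() -> Alignment:
    cfg = SimConfig(S=12, L=30, branch_length=0.4, seed=13,
                    gap_profile=np.full(30, 0.15))
    aln, _ = simulate_structural_alignment(cfg)
    return aln


def brute_force_pairwise_identity(aln: Alignment) -> float:
    """Independent oracle: plain double loop over rows and columns."""
    vals = []
    for a in range(aln.S):
        for b in range(a + 1, aln.S):
            same = both = 0
            for x, y in zip(aln.rows[a], aln.rows[b]):
                if x in "ACGU" and y in "ACGU":
                    both += 1
                    if x == y:
                        same += 1
            if both:
                vals.append(same / both)
    return sum(vals) / len(vals)
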