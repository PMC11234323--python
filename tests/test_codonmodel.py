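import math

import numpy as np
import pytest

from covarna import codonmodel as cm
from covarna.msa_io import Alignment


@pytest.fixture(scope="module")
def model():
    return cm.build_amino_model()


@pytest.fixture(scope="module")
def bias():
    return cm.uniform_codon_bias()


class TestGeneticCode:
    def test_61_sense_codons(self):
        code = cm.standard_genetic_code()
        assert len(code.codons) == 61
        assert "UAA" not in code.codon_to_aa
        assert "UAG" not in code.codon_to_aa
        assert "UGA" not in code.codon_to_aa

    def test_six_box_amino_acids(self):
        code = cm.standard_genetic_code()
        assert sorted(code.six_box_amino_acids()) == ["L", "R", "S"]

    def test_single_codon_amino_acids(self):
        code = cm.standard_genetic_code()
        boxes = code.aa_to_codons
        assert boxes["M"] == ("AUG",)
        assert boxes["W"] == ("UGG",)

    def test_63_alternative_codons(self):
        # enumerating the 4^3 codon space, any fixed codon has 63 others
        space = [a + b + c for a in "ACGU" for b in "ACGU" for c in "ACGU"]
        assert len(space) == 64
        assert sum(1 for c in space if c != "AUG") == 63


class TestCodonBias:
    def test_uniform_sums_to_one(self, bias):
        for aa, dist in bias.probs.items():
            assert sum(dist.values()) == pytest.approx(1.0)

    def test_counts_table(self, tmp_path):
        p = tmp_path / "bias.tsv"
        p.write_text("TGT\t30\nTGC\t10\nATG\t7\n# comment\n")
        b = cm.codon_bias_from_counts(p)
        assert b.probs["C"]["UGU"] == pytest.approx(0.75)
        assert b.probs["C"]["UGC"] == pytest.approx(0.25)
        assert b.probs["M"]["AUG"] == pytest.approx(1.0)
        # uncounted amino acids fall back to uniform
        assert b.probs["G"]["GGA"] == pytest.approx(0.25)

    def test_mass_on_wrong_codon_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            cm.CodonBias(probs={"M": {"UGG": 1.0}})


class TestAminoAcidModel:
    def test_t0_identity(self, model):
        assert np.allclose(model.transition(0.0), np.eye(20))

    def test_rows_stochastic(self, model):
        p = model.transition(0.2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(p >= -1e-12)

    def test_rate_normalization_one_sub_per_site(self, model):
        # sum_a pi_a * (-R_aa) = 1 exactly by construction
        assert model.expected_substitutions(1.0) == pytest.approx(1.0, abs=1e-6)

    def test_stationary_preserved(self, model):
        p = model.transition(5.0)
        assert np.allclose(model.pi @ p, model.pi, atol=1e-8)

    def test_negative_time_rejected(self, model):
        with pytest.raises(ValueError):
            model.transition(-0.1)


class TestCodonDistribution:
    def test_t0_equals_bias(self, model, bias):
        dist = cm.codon_distribution("G", 0.0, bias, model)
        code = cm.standard_genetic_code()
        for codon, prob in zip(dist.codons, dist.probs):
            expected = bias.probs["G"].get(codon, 0.0)
            assert prob == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("aa", list(cm.AMINO_ACIDS))
    @pytest.mark.parametrize("t", [0.0, 0.2, 1.0])
    def test_sums_to_one(self, model, bias, aa, t):
        dist = cm.codon_distribution(aa, t, bias, model)
        assert dist.probs.sum() == pytest.approx(1.0)

    def test_cysteine_wobble_split(self, model, bias):
        # Cys at t=0 with uniform bias: 0.5 on UGU, 0.5 on UGC
        dist = cm.codon_distribution("C", 0.0, bias, model)
        probs = dict(zip(dist.codons, dist.probs))
        assert probs["UGU"] == pytest.approx(0.5)
        assert probs["UGC"] == pytest.approx(0.5)

    def test_marginals_consistent_with_joint(self, model, bias):
        dist = cm.codon_distribution("S", 0.3, bias, model)
        for pair in ("c1c2", "c1c3", "c2c3"):
            assert dist.marginal_pair(pair).sum() == pytest.approx(1.0)

    def test_unknown_pair_label_rejected(self, model, bias):
        dist = cm.codon_distribution("S", 0.1, bias, model)
        with pytest.raises(ValueError, match="pair"):
            dist.marginal_pair("c3c1")


class TestWithinCodonMI:
    def test_tryptophan_zero_at_t0(self, model, bias):
        for pair in ("c1c2", "c1c3", "c2c3"):
            assert cm.within_codon_mi("W", 0.0, pair, bias, model) == pytest.approx(0.0)

    def test_arginine_c1c2_zero_at_t0(self, model, bias):
        # c2 is fixed (always G) for Arg codons: degenerate marginal, MI 0
        assert cm.within_codon_mi("R", 0.0, "c1c2", bias, model) == pytest.approx(0.0, abs=1e-12)

    def test_serine_t0_matches_brute_force(self, model, bias):
        # independent oracle: enumerate the 6 serine codons uniformly and
        # sum the 16 joint cells by hand
        codons = ["UCU", "UCC", "UCA", "UCG", "AGU", "AGC"]
        idx = {c: i for i, c in enumerate("ACGU")}
        joint = np.zeros((4, 4))
        for codon in codons:
            joint[idx[codon[0]], idx[codon[1]]] += 1 / 6
        pi = joint.sum(axis=1)
        pj = joint.sum(axis=0)
        oracle = sum(joint[a, b] * math.log2(joint[a, b] / (pi[a] * pj[b]))
                     for a in range(4) for b in range(4) if joint[a, b] > 0)
        assert cm.within_codon_mi("S", 0.0, "c1c2", bias, model) == pytest.approx(oracle, abs=1e-12)

    def test_mi_zero_when_marginal_degenerate(self, model, bias):
        # proline: CCN, c1 and c2 both fixed
        assert cm.within_codon_mi("P", 0.0, "c1c2", bias, model) == pytest.approx(0.0, abs=1e-12)


class TestTrajectories:
    def test_singleton_grid(self, model, bias):
        series = cm.mi_trajectory("S", "c1c2", [0.2], bias, model)
        assert series.shape == (1,)

    def test_six_box_dominant_pairs_decrease(self, model, bias):
        # serine's synonymous pairs and the c1-c3 pairs of arginine and
        # leucine decay with divergence: strictly decreasing until below 5%
        # of the starting value and pinned under that floor afterwards
        # (late nonsynonymous mixing adds a wiggle invisible at plot scale)
        grid = np.linspace(0.05, 2.0, 30)
        for aa, pair in (("S", "c1c2"), ("S", "c2c3"), ("R", "c1c3"),
                         ("L", "c1c3")):
            traj = cm.mi_trajectory(aa, pair, grid, bias, model)
            floor = 0.05 * traj[0]
            above = traj >= floor
            head = traj[above]
            assert np.all(np.diff(head) < 0), (aa, pair)
            assert np.all(traj[~above] < floor), (aa, pair)
            assert traj[-1] < 0.5 * traj[0]

    def test_single_codon_amino_acids_rise_from_zero(self, model, bias):
        for aa in ("M", "W"):
            assert cm.total_within_codon_mi(aa, 0.0, bias, model) == pytest.approx(0.0)
            assert cm.total_within_codon_mi(aa, 0.3, bias, model) > 0.1

    def test_bad_grid_rejected(self, model, bias):
        with pytest.raises(ValueError):
            cm.mi_trajectory("S", "c1c2", [], bias, model)
        with pytest.raises(ValueError):
            cm.mi_trajectory("S", "c1c2", [-0.5, 0.2], bias, model)

    def test_scaled_comparison_preserves_rank_order(self, model, bias):
        # scaling a set of MI values to sum one is monotone
        vals = np.array([cm.total_within_codon_mi(a, 0.2, bias, model)
                         for a in cm.AMINO_ACIDS])
        scaled = vals / vals.sum()
        assert list(np.argsort(vals)) == list(np.argsort(scaled))


class TestExonSimulation:
    def test_t0_deterministic_bias_identical_rows(self, model):
        code = cm.standard_genetic_code()
        probs = {aa: {cs[0]: 1.0} for aa, cs in code.aa_to_codons.items()}
        deterministic = cm.CodonBias(probs=probs)
        aln = cm.simulate_exon_alignment("MWACD", 0.0, 6, deterministic,
                                         model, seed=1)
        assert len(set(aln.rows)) == 1
        assert aln.L == 15

    def test_rna_alphabet_no_gaps(self, model, bias):
        aln = cm.simulate_exon_alignment("SRL", 0.2, 10, bias, model, seed=2)
        assert isinstance(aln, Alignment)
        assert not aln.gap_mask().any()

    def test_empirical_frequencies_converge(self, model, bias):
        # law of large numbers: empirical codon frequencies at one site
        # approach the model distribution (chi-square sanity bound)
        from scipy.stats import chisquare
        aa, t, n = "S", 0.2, 4000
        dist = cm.codon_distribution(aa, t, bias, model)
        aln = cm.simulate_exon_alignment(aa, t, n, bias, model, seed=3)
        counts = {}
        for row in aln.rows:
            counts[row] = counts.get(row, 0) + 1
        keep = dist.probs * n >= 5
        observed = np.array([counts.get(c, 0)
                             for c, k in zip(dist.codons, keep) if k])
        expected = np.array([p * n for p, k in zip(dist.probs, keep) if k])
        # renormalize over the kept cells
        chi2, p = chisquare(observed, expected * observed.sum() / expected.sum())
        assert p > 1e-4

    def test_reproducible(self, model, bias):
        a1 = cm.simulate_exon_alignment("SRLC", 0.2, 8, bias, model, seed=9)
        a2 = cm.simulate_exon_alignment("SRLC", 0.2, 8, bias, model, seed=9)
        assert a1.rows == a2.rows
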