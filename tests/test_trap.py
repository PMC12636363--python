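import math

import numpy as np
import pytest

import streakscan as sk
from streakscan.trap import DifferentialConfig, default_r0

from conftest import random_pfm


def energy_of_word(e, word):
    from streakscan.motifs import BASE_INDEX

    return sum(e.eps[i, BASE_INDEX[b]] for i, b in enumerate(word))


class TestPfmToEnergy:
    def test_pure_column_energies(self):
        m = sk.MotifModel(id="p", pfm=np.array([[10.0, 0, 0, 0]]))
        e = sk.pfm_to_energy(m, sk.TrapParams(lambda_=1.0, r0=1.0), pseudocount=1.0)
        assert e.eps[0].tolist() == pytest.approx([0.0] + [math.log(11.0)] * 3)

    def test_uniform_column_all_zero(self):
        m = sk.MotifModel(id="u", pfm=np.full((2, 4), 7.0))
        e = sk.pfm_to_energy(m, sk.TrapParams(r0=1.0))
        assert np.all(e.eps == 0.0)

    def test_lambda_scales_energies(self):
        m = sk.MotifModel(id="r", pfm=random_pfm(5, 2))
        e1 = sk.pfm_to_energy(m, sk.TrapParams(lambda_=1.0, r0=1.0))
        e2 = sk.pfm_to_energy(m, sk.TrapParams(lambda_=2.0, r0=1.0))
        assert np.allclose(e2.eps, e1.eps / 2.0)

    def test_default_r0_grows_with_width(self):
        assert default_r0(10) > default_r0(5) > 0

    def test_column_minimum_is_zero(self):
        m = sk.MotifModel(id="r", pfm=random_pfm(6, 9))
        e = sk.pfm_to_energy(m)
        assert np.allclose(e.eps.min(axis=1), 0.0)


class TestWindowOccupancy:
    def _energy(self, r0=1.0):
        m = sk.MotifModel(id="c", pfm=np.array([[10.0, 0, 0, 0]] * 3))
        return sk.pfm_to_energy(m, sk.TrapParams(lambda_=1.0, r0=r0))

    def test_consensus_at_unit_strength_is_half(self):
        assert sk.window_occupancy(self._energy(), "AAA") == pytest.approx(0.5)

    def test_strength_three_gives_three_quarters(self):
        assert sk.window_occupancy(self._energy(r0=3.0), "AAA") == pytest.approx(0.75)

    def test_decreasing_in_energy_increasing_in_strength(self):
        e = self._energy()
        occs = [sk.window_occupancy(e, w) for w in ["AAA", "AAC", "ACC", "CCC"]]
        assert all(a > b for a, b in zip(occs, occs[1:]))
        assert sk.window_occupancy(self._energy(5.0), "ACC") > sk.window_occupancy(
            self._energy(0.5), "ACC"
        )

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            sk.window_occupancy(self._energy(), "AAX")


class TestSequenceAffinity:
    def test_single_consensus_window(self):
        m = sk.MotifModel(id="c", pfm=np.array([[10.0, 0, 0, 0]] * 3))
        e = sk.pfm_to_energy(m, sk.TrapParams(r0=1.0, both_strands=False))
        assert sk.sequence_affinity(e, "AAA").affinity == pytest.approx(0.5)

    @pytest.mark.parametrize("both_strands", [False, True])
    def test_matches_per_window_oracle(self, both_strands):
        e = sk.pfm_to_energy(
            sk.MotifModel(id="r", pfm=random_pfm(5, 4)),
            sk.TrapParams(both_strands=both_strands),
        )
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), 61))
        expected = sum(
            sk.window_occupancy(e, seq[i : i + 5]) for i in range(len(seq) - 4)
        )
        if both_strands:
            rc = sk.reverse_complement(seq)
            expected += sum(
                sk.window_occupancy(e, rc[i : i + 5]) for i in range(len(rc) - 4)
            )
        assert sk.sequence_affinity(e, seq).affinity == pytest.approx(expected)

    def test_concatenation_only_adds_affinity(self):
        e = sk.pfm_to_energy(sk.MotifModel(id="r", pfm=random_pfm(4, 6)))
        a = sk.sequence_affinity(e, "ACGTACGT").affinity
        b = sk.sequence_affinity(e, "TTTTGGGG").affinity
        joint = sk.sequence_affinity(e, "ACGTACGT" + "TTTTGGGG").affinity
        assert joint >= max(a, b)

    def test_short_sequence_zero_affinity(self):
        e = sk.pfm_to_energy(sk.MotifModel(id="r", pfm=random_pfm(8, 6)))
        assert sk.sequence_affinity(e, "ACG").affinity == 0.0

    def test_reverse_strand_negligible_for_ac_rich_motif(self, cabl_pfm_model):
        """The A/C-rich consensus reads G/T-rich on the minus strand, so
        both-strand affinity of the wild-type streak is dominated by the
        forward strand."""
        fwd = sk.pfm_to_energy(cabl_pfm_model, sk.TrapParams(both_strands=False))
        both = sk.pfm_to_energy(cabl_pfm_model, sk.TrapParams(both_strands=True))
        a_fwd = sk.sequence_affinity(fwd, sk.WT_STREAK).affinity
        a_both = sk.sequence_affinity(both, sk.WT_STREAK).affinity
        assert a_both - a_fwd < 0.05 * a_fwd


class TestAffinityPvalue:
    def _energy(self):
        return sk.pfm_to_energy(sk.MotifModel(id="r", pfm=random_pfm(5, 4)))

    def test_zero_affinity_has_p_one(self):
        e = self._energy()
        p = sk.affinity_pvalue(0.0, e, np.full(4, 0.25), seq_len=30, n_samples=200, seed=1)
        assert p == 1.0

    def test_unreachable_affinity_hits_add_one_floor(self):
        e = self._energy()
        p = sk.affinity_pvalue(1e9, e, np.full(4, 0.25), seq_len=30, n_samples=200, seed=1)
        assert p == pytest.approx(1 / 201)

    def test_seeded_reruns_are_bit_identical(self):
        e = self._energy()
        args = dict(bg=np.full(4, 0.25), seq_len=40, n_samples=500, seed=77)
        assert sk.affinity_pvalue(1.0, e, **args) == sk.affinity_pvalue(1.0, e, **args)

    def test_background_draws_give_uniformish_pvalues(self):
        """p-values of background-drawn sequences should be calibrated:
        mean near 0.5 over replicates."""
        e = self._energy()
        bg = np.full(4, 0.25)
        rng = np.random.default_rng(123)
        from streakscan.trap import sample_background_affinities

        null = sample_background_affinities(e, bg, 40, 4000, np.random.default_rng(5))
        ps = []
        for _ in range(200):
            seq_codes = rng.choice(4, size=40)
            seq = "".join("ACGT"[c] for c in seq_codes)
            a = sk.sequence_affinity(e, seq).affinity
            ps.append(sk.affinity_pvalue(a, e, bg, 40, null_affinities=null))
        assert 0.45 <= np.mean(ps) <= 0.55


class TestDifferentialAffinity:
    def _energy(self, cabl_pfm_model):
        return sk.pfm_to_energy(cabl_pfm_model)

    def test_identical_windows_not_flagged(self, cabl_pfm_model):
        w = sk.SequenceWindow(sequence=sk.WT_STREAK, origin=1)
        res = sk.differential_affinity(w, w, self._energy(cabl_pfm_model),
                                       DifferentialConfig(n_samples=500))
        assert res.log2_ratio == 0.0
        assert not res.flagged

    def test_mutant_allele_loses_affinity(self, cabl_pfm_model):
        ref = sk.SequenceWindow(sequence=sk.WT_STREAK, origin=1, allele_label="ref")
        alt = sk.SequenceWindow(sequence=sk.MT_STREAK, origin=1, allele_label="alt")
        res = sk.differential_affinity(ref, alt, self._energy(cabl_pfm_model),
                                       DifferentialConfig(n_samples=2000, seed=3))
        assert res.log2_ratio < 0
        assert res.affinity_ref > res.affinity_alt

    def test_swapping_alleles_negates_ratio(self, cabl_pfm_model):
        ref = sk.SequenceWindow(sequence=sk.WT_STREAK, origin=1)
        alt = sk.SequenceWindow(sequence=sk.MT_STREAK, origin=1)
        e = self._energy(cabl_pfm_model)
        cfg = DifferentialConfig(n_samples=200, seed=3)
        fwd = sk.differential_affinity(ref, alt, e, cfg)
        rev = sk.differential_affinity(alt, ref, e, cfg)
        assert fwd.log2_ratio == pytest.approx(-rev.log2_ratio)

    def test_length_mismatch_rejected(self, cabl_pfm_model):
        a = sk.SequenceWindow(sequence="ACGTACGTAC", origin=1)
        b = sk.SequenceWindow(sequence="ACGT", origin=1)
        with pytest.raises(ValueError):
            sk.differential_affinity(a, b, self._energy(cabl_pfm_model))

    def test_consensus_windows_beat_matched_random_windows(self, cabl_pfm_model):
        """Planted-motif recovery: a window containing the consensus word
        should out-score a matched random window nearly always."""
        e = self._energy(cabl_pfm_model)
        rng = np.random.default_rng(31)
        wins = 0
        n_trials = 100
        for _ in range(n_trials):
            bg = "".join(rng.choice(list("ACGT"), 40))
            pos = int(rng.integers(0, 40 - 8))
            planted = bg[:pos] + "AAAACAAA" + bg[pos + 8 :]
            random_win = "".join(rng.choice(list("ACGT"), 40))
            a_p = sk.sequence_affinity(e, planted).affinity
            a_r = sk.sequence_affinity(e, random_win).affinity
            wins += a_p > a_r
        assert wins >= 95
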