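"""Codon alignment construction and the NG86 / YN00 estimators."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctldcp.codons import SENSE_CODONS
from ctldcp.kaks import (
    CodonAlignment,
    backthread_codons,
    codon_alignment_from_cds,
    map_protein_interval_to_cds,
    ng86,
    yn00,
)

from _oracles import oracle_ng86_counts
from conftest import random_cds


class TestCoordinateMapping:
    @pytest.mark.parametrize(
        "interval,expected", [((10, 20), (28, 60)), ((1, 1), (1, 3))]
    )
    def test_closed_form(self, interval, expected):
        assert map_protein_interval_to_cds(*interval) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError, match="beyond CDS"):
            map_protein_interval_to_cds(200, 210, cds_length=600)

    def test_invalid_interval_raises(self):
        with pytest.raises(ValueError):
            map_protein_interval_to_cds(5, 4)


class TestBackthread:
    def test_ungapped_pair(self):
        aln = backthread_codons("MK", "MK", "ATGAAA", "ATGAAG")
        assert len(aln) == 2
        assert aln.codons_a == ("ATG", "AAA")

    def test_gap_column_dropped(self):
        aln = backthread_codons("M-K", "MQK", "ATGAAA", "ATGCAAAAA")
        assert len(aln) == 2
        assert aln.dropped["gap"] == 1
        assert aln.retained_columns == (1, 3)

    def test_internal_stop_column_dropped_and_reported(self):
        # '*'-free protein strings are not accepted, so thread via the
        # equal-length CDS helper with a mid-frame TAA
        aln = backthread_codons("M*K".replace("*", "Y"), "MYK", "ATGTAAAAA", "ATGTACAAA")
        assert aln.dropped["stop"] == 1
        assert len(aln) == 2

    def test_ambiguous_codon_dropped(self):
        aln = backthread_codons("MK", "MK", "ATGAAN", "ATGAAA")
        assert aln.dropped["ambiguous"] == 1
        assert len(aln) == 1

    def test_translation_mismatch_names_residue(self):
        with pytest.raises(ValueError, match="residue 2"):
            backthread_codons("MK", "MK", "ATGCCC", "ATGAAA")


class TestNg86:
    def test_identical_sequences(self, rng):
        cds = random_cds(rng, 300)
        res = ng86(codon_alignment_from_cds(cds, cds))
        assert res.Sd == res.Nd == 0
        assert res.dN == 0 and res.dS == 0
        assert math.isnan(res.ratio)

    def test_hand_enumerated_phe_leu_pair(self):
        """TTT vs TTA: hand enumeration of degeneracies with stop exclusion."""
        res = ng86(codon_alignment_from_cds("TTT", "TTA"))
        assert res.S == pytest.approx(0.5)
        assert res.N == pytest.approx(2.5)
        assert (res.Sd, res.Nd) == (0.0, 1.0)
        assert res.pN == pytest.approx(0.4)
        assert res.dN == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))
        assert res.dS == 0.0
        assert math.isnan(res.ratio)

    def test_all_sense_codon_pairs_match_oracle(self):
        """Exact oracle agreement on every 61 x 61 codon pair."""
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            aln = CodonAlignment((ca,), (cb,), (1,))
            res = ng86(aln)
            S, N, Sd, Nd = oracle_ng86_counts((ca,), (cb,))
            assert res.S == pytest.approx(S, abs=1e-12), (ca, cb)
            assert res.N == pytest.approx(N, abs=1e-12)
            assert res.Sd == pytest.approx(Sd, abs=1e-12), (ca, cb)
            assert res.Nd == pytest.approx(Nd, abs=1e-12)

    def test_random_alignments_match_oracle(self, rng):
        for _ in range(25):
            aln = codon_alignment_from_cds(random_cds(rng, 100), random_cds(rng, 100))
            res = ng86(aln)
            S, N, Sd, Nd = oracle_ng86_counts(aln.codons_a, aln.codons_b)
            assert res.S == pytest.approx(S)
            assert res.Sd == pytest.approx(Sd)
            assert res.Nd == pytest.approx(Nd)

    def test_zero_columns_raises(self):
        with pytest.raises(ValueError):
            ng86(CodonAlignment((), (), ()))


class TestYn00:
    def test_identical_sequences(self, rng):
        cds = random_cds(rng, 200)
        res = yn00(codon_alignment_from_cds(cds, cds))
        assert res.dN == 0 and res.dS == 0
        assert math.isnan(res.ratio)

    def test_reduces_to_ng86_at_kappa_one_uniform(self, rng):
        """With kappa=1 and uniform frequencies YN00 collapses onto NG86."""
        for _ in range(25):
            aln = codon_alignment_from_cds(random_cds(rng, 60), random_cds(rng, 60))
            r_ng = ng86(aln)
            r_yn = yn00(aln, kappa=1.0, codon_freqs="uniform")
            for a, b in ((r_ng.S, r_yn.S), (r_ng.Sd, r_yn.Sd),
                         (r_ng.dN, r_yn.dN), (r_ng.dS, r_yn.dS)):
                if math.isnan(a) or math.isnan(b):
                    assert math.isnan(a) and math.isnan(b)
                else:
                    assert abs(a - b) < 1e-6

    def test_kappa_estimated_above_one_under_transition_bias(self, rng):
        from ctldcp.simulate import simulate_codon_evolution

        kappas = []
        for seed in range(10):
            anc = random_cds(rng, 400)
            a, b = simulate_codon_evolution(anc, omega=1.0, kappa=4.0, t=0.4, rng=rng)
            kappas.append(yn00(codon_alignment_from_cds(a, b)).kappa)
        assert np.median(kappas) > 2.0

    def test_converged_flag_set(self, rng):
        res = yn00(codon_alignment_from_cds(random_cds(rng, 50), random_cds(rng, 50)))
        assert res.converged


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from(["ng86", "yn00"]))
def test_site_count_conservation_and_symmetry(seed, method):
    """S + N = 3 x columns, and the estimators are symmetric in the pair."""
    from ctldcp.kaks import ESTIMATORS

    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 80))
    cds_a, cds_b = random_cds(rng, n), random_cds(rng, n)
    aln = codon_alignment_from_cds(cds_a, cds_b)
    est = ESTIMATORS[method]
    res = est(aln)
    assert res.S + res.N == pytest.approx(3 * len(aln), abs=1e-9)
    assert res.S >= 0 and res.N >= 0
    assert res.Sd + res.Nd <= 3 * len(aln) + 1e-9
    swapped = est(CodonAlignment(aln.codons_b, aln.codons_a, aln.retained_columns))
    assert swapped.S == pytest.approx(res.S)
    assert swapped.Sd == pytest.approx(res.Sd)
    for a, b in ((swapped.dN, res.dN), (swapped.dS, res.dS)):
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


def test_monotonic_in_true_omega(rng):
    """Mean estimated Ka/Ks increases with the generating omega."""
    from ctldcp.simulate import simulate_codon_evolution

    means = []
    for omega in (0.2, 1.0, 3.0):
        ratios = []
        for _ in range(15):
            anc = random_cds(rng, 300)
            a, b = simulate_codon_evolution(anc, omega=omega, kappa=2.0, t=0.3, rng=rng)
            r = ng86(codon_alignment_from_cds(a, b))
            if math.isfinite(r.ratio):
                ratios.append(r.ratio)
        means.append(np.mean(ratios))
    assert means[0] < means[1] < means[2]
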