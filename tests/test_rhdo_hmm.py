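"""HMM core: emission fractions and likelihoods, genetic-map transitions,
Viterbi decoding against brute force, and the genotype-call rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplonipt import rhdo_hmm as hmm
from haplonipt import validation
from haplonipt.genetic_map import GeneticMap, R_MIN, recombination_fraction, transition_matrix
from haplonipt.types import Category, HaplotypePath, MatSubtype, State


class TestExpectedFractions:
    def test_maternal_father_hom_p_values(self):
        f = 0.10
        assert hmm.expected_allele_fraction(
            State.P, Category.MAT_INFORMATIVE, MatSubtype.FATHER_HOM_P, f) == pytest.approx(0.55)
        assert hmm.expected_allele_fraction(
            State.N, Category.MAT_INFORMATIVE, MatSubtype.FATHER_HOM_P, f) == pytest.approx(0.5)

    def test_maternal_father_hom_n_values(self):
        f = 0.10
        assert hmm.expected_allele_fraction(
            State.P, Category.MAT_INFORMATIVE, MatSubtype.FATHER_HOM_N, f) == pytest.approx(0.5)
        assert hmm.expected_allele_fraction(
            State.N, Category.MAT_INFORMATIVE, MatSubtype.FATHER_HOM_N, f) == pytest.approx(0.45)

    def test_paternal_absent_allele_floors_at_epsilon(self):
        f = 0.10
        assert hmm.expected_allele_fraction(
            State.P, Category.PAT_INFORMATIVE, None, f) == pytest.approx(0.05)
        assert hmm.expected_allele_fraction(
            State.N, Category.PAT_INFORMATIVE, None, f) == pytest.approx(0.005)

    def test_vanishing_ff_collapses_states(self):
        f = 1e-9
        for cat, subs in [
            (Category.MAT_INFORMATIVE, [MatSubtype.FATHER_HOM_P, MatSubtype.FATHER_HOM_N]),
            (Category.PAT_INFORMATIVE, [None, "MOTHER_HAS_P"]),
        ]:
            for sub in subs:
                p = hmm.expected_allele_fraction(State.P, cat, sub, f)
                n = hmm.expected_allele_fraction(State.N, cat, sub, f)
                assert p == pytest.approx(n, abs=1e-8)

    def test_matches_mixture_simulation(self):
        # MAT subtype father-hom-P at f=0.10: generator mean ~ 0.55
        from conftest import diplotype, tiny_panel
        from haplonipt import simdata

        panel = tiny_panel([100, 200])
        mom = diplotype([1, 1], [0, 0], "m", pathogenic_hap=1)  # alt on P hap
        dad = diplotype([1, 1], [1, 1], "d")
        truth = simdata.SimTruth(np.array([1, 1]), np.array([1, 1]), [], 0.10, 0)
        counts = simdata.simulate_plasma_counts(mom, dad, truth, panel,
                                                depth_mean=200_000, error_rate=0.0, seed=5)
        frac = counts.alt_count[0] / counts.depth[0]
        assert frac == pytest.approx(0.55, abs=0.005)

    def test_invalid_ff_rejected(self):
        with pytest.raises(ValueError):
            hmm.expected_allele_fraction(State.P, Category.MAT_INFORMATIVE,
                                         MatSubtype.FATHER_HOM_P, 0.0)


class TestEmission:
    def test_hand_computed_binomial(self):
        # C(2,1) * 0.5 * 0.5 = 0.5
        assert hmm.emission_logprob(1, 1, 0.5) == pytest.approx(math.log(0.5))

    def test_zero_depth_is_uninformative(self):
        assert hmm.emission_logprob(0, 0, 0.3) == 0.0

    def test_symmetric_at_half(self):
        assert hmm.emission_logprob(7, 3, 0.5) == pytest.approx(hmm.emission_logprob(3, 7, 0.5))

    @pytest.mark.parametrize("depth,frac", [(1, 0.5), (7, 0.3), (25, 0.05)])
    def test_normalisation_over_counts(self, depth, frac):
        total = sum(math.exp(hmm.emission_logprob(k, depth - k, frac))
                    for k in range(depth + 1))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestTransitions:
    def test_zero_distance_floored(self):
        t = transition_matrix(0.0)
        assert t[0, 1] == R_MIN
        assert t[0, 0] == 1.0 - R_MIN

    def test_large_distance_asymptote(self):
        t = transition_matrix(1e6)
        assert t[0, 1] == pytest.approx(0.5)

    def test_one_centimorgan_closed_form(self):
        r = float(recombination_fraction(1.0))
        assert r == pytest.approx((1 - math.exp(-0.02)) / 2, abs=1e-12)
        assert r == pytest.approx(0.009901, abs=1e-6)

    @given(st.floats(0.0, 1000.0))
    @settings(deadline=None)
    def test_rows_sum_to_one_and_r_bounded(self, d):
        t = transition_matrix(d)
        assert np.allclose(t.sum(axis=1), 1.0)
        assert R_MIN <= t[0, 1] <= 0.5

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-1.0)

    def test_map_interpolation_clamps_outside_anchors(self):
        gmap = GeneticMap(np.array([100, 200]), np.array([0.0, 1.0]))
        assert gmap.cm_at(150) == pytest.approx(0.5)
        assert gmap.cm_at(50) == 0.0  # clamped
        assert gmap.cm_at(400) == 1.0


class TestViterbi:
    def test_single_snp_strong_p(self, uniform_map):
        path = hmm.viterbi_decode(np.array([4_500_000]), np.array([90]),
                                  np.array([10]), np.array([0.55]),
                                  np.array([0.5]), uniform_map)
        assert path.states.tolist() == [True]
        assert len(path.segments) == 1

    def test_all_p_simulation_decodes_all_p(self, uniform_map):
        rng_master = np.random.default_rng(0)
        f = 0.15
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            n = 10
            pos = np.sort(rng.choice(np.arange(4_100_000, 5_900_000), n, replace=False))
            depth = rng.poisson(200, n)
            fP, fN = np.full(n, (1 + f) / 2), np.full(n, 0.5)
            pc = rng.binomial(depth, fP)
            path = hmm.viterbi_decode(pos, pc, depth - pc, fP, fN, uniform_map)
            assert np.all(path.states)

    def test_matches_exhaustive_enumeration(self):
        assert validation.viterbi_exhaustive_agreement(100, seed=3) == 1.0

    def test_ties_break_toward_stay(self, uniform_map):
        # no data at all: every path has equal emission probability, so
        # the decoder must return a constant (no-switch) path
        n = 6
        pos = np.linspace(4_100_000, 5_900_000, n).astype(np.int64)
        zero = np.zeros(n, np.int64)
        path = hmm.viterbi_decode(pos, zero, zero, np.full(n, 0.6),
                                  np.full(n, 0.4), uniform_map)
        assert len(path.segments) == 1


class TestCallRules:
    def _path(self, positions, states):
        return HaplotypePath("mat", np.asarray(positions),
                             np.asarray(states, bool), 0.0)

    def test_single_segment_spanning_gene(self):
        path = self._path([100, 200, 300], [1, 1, 1])
        call = hmm.call_fetal_allele(path, (150, 250))
        assert call.allele == "P"

    def test_two_segments_one_spans_gene(self):
        # crossover downstream of the gene: the spanning segment wins
        path = self._path([100, 200, 300, 400], [1, 1, 1, 0])
        call = hmm.call_fetal_allele(path, (120, 180))
        assert call.allele == "P"
        path2 = self._path([100, 200, 300, 400], [0, 1, 1, 1])
        assert hmm.call_fetal_allele(path2, (250, 350)).allele == "P"

    def test_boundary_inside_gene_is_no_call(self):
        path = self._path([100, 200, 300, 400], [1, 1, 0, 0])
        call = hmm.call_fetal_allele(path, (150, 350))
        assert call.allele == "NO_CALL"
        assert "boundary" in call.reason

    def test_three_segments_need_unique_spanning_segment(self):
        path = self._path([100, 200, 300, 400, 500], [0, 1, 1, 1, 0])
        assert hmm.call_fetal_allele(path, (250, 350)).allele == "P"
        path2 = self._path([100, 200, 300, 400, 500], [0, 1, 0, 1, 0])
        assert hmm.call_fetal_allele(path2, (150, 450)).allele == "NO_CALL"

    def test_gene_outside_snp_coverage_is_no_call(self):
        path = self._path([100, 200], [1, 1])
        call = hmm.call_fetal_allele(path, (300, 400))
        assert call.allele == "NO_CALL"
        assert "not covered" in call.reason

    def test_empty_path_is_no_call(self):
        path = HaplotypePath("pat", np.array([]), np.array([], bool), 0.0)
        assert hmm.call_fetal_allele(path, (1, 2)).allele == "NO_CALL"


class TestRecombinationScenarios:
    def test_crossover_inside_gene_forces_no_call(self):
        allele, n_seg = validation.crossover_case(inside_gene=True)
        assert allele == "NO_CALL"

    def test_crossover_outside_gene_gives_two_segment_call(self):
        allele, n_seg = validation.crossover_case(inside_gene=False)
        assert allele == "P" and n_seg == 2
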