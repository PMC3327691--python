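"""Call-error model: HWE loci, joint call law, and moments of Delta."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpower import (
    ErrorRates,
    LocusModel,
    delta_moments,
    equivalence_contour,
    joint_call_distribution,
    make_locus_model,
    sample_observed_calls,
    sd_delta_table,
)
from cnvpower.locus import delta_moments_from_joint


class TestMakeLocusModel:
    def test_deletion_hwe_expansion(self):
        locus = make_locus_model("deletion", 0.1)
        assert np.allclose(locus.freqs, (0.01, 0.18, 0.81, 0.0, 0.0))

    def test_duplication_mirrors_deletion(self):
        locus = make_locus_model("duplication", 0.1)
        assert np.allclose(locus.freqs, (0.0, 0.0, 0.81, 0.18, 0.01))

    def test_multiallelic_trinomial_with_del_dup_het_in_state2(self):
        locus = make_locus_model("multiallelic", 0.1, 0.1)
        # g2 = 0.8^2 + 2 * 0.1 * 0.1: the del/dup heterozygote has copy number 2
        assert np.allclose(locus.freqs, (0.01, 0.16, 0.66, 0.16, 0.01))

    def test_zero_allele_frequency_is_monomorphic(self):
        assert make_locus_model("deletion", 0.0).freqs == (0, 0, 1, 0, 0)

    @pytest.mark.parametrize(
        "kind,freqs",
        [("deletion", (0.6,)), ("deletion", (-0.1,)), ("deletion", (0.1, 0.1)),
         ("multiallelic", (0.1,)), ("nonsense", (0.1,))],
    )
    def test_invalid_inputs_rejected(self, kind, freqs):
        with pytest.raises(ValueError):
            make_locus_model(kind, *freqs)

    def test_locus_invariants_enforced(self):
        with pytest.raises(ValueError):
            LocusModel("deletion", (0.1, 0.1, 0.6, 0.2, 0.0))  # state 3 at a deletion locus
        with pytest.raises(ValueError):
            LocusModel("deletion", (0.1, 0.1, 0.7, 0.0, 0.0))  # does not sum to 1


class TestJointCallDistribution:
    def test_no_errors_gives_diagonal(self, multiallelic_locus):
        joint = joint_call_distribution(multiallelic_locus, ErrorRates(0.0, 0.0))
        assert np.allclose(joint.probs, np.diag(multiallelic_locus.g))

    def test_false_negative_routes_to_reference(self, deletion_locus):
        joint = joint_call_distribution(deletion_locus, ErrorRates(nu_p=0.0, nu_n=0.5))
        assert joint.probs[1, 2] == pytest.approx(0.09)  # 0.18 * 0.5
        assert joint.probs[1, 1] == pytest.approx(0.09)

    def test_false_positive_redistributed_by_genotype_frequency(self, multiallelic_locus):
        joint = joint_call_distribution(multiallelic_locus, ErrorRates(nu_p=0.05, nu_n=0.0))
        assert joint.probs[2, 1] == pytest.approx(0.66 * 0.05 * 0.16 / 0.34)

    def test_false_positive_without_destination_rejected(self):
        mono = make_locus_model("deletion", 0.0)
        with pytest.raises(ValueError):
            joint_call_distribution(mono, ErrorRates(nu_p=0.1, nu_n=0.0))

    @given(
        q=st.floats(0.01, 0.5),
        nu_n=st.floats(0.0, 1.0),
        nu_p=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_normalization_and_marginals(self, q, nu_n, nu_p):
        locus = make_locus_model("multiallelic", q, q / 2)
        joint = joint_call_distribution(locus, ErrorRates(nu_p=nu_p, nu_n=nu_n))
        assert joint.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(joint.marginal_true(), locus.g, atol=1e-12)


class TestDeltaMoments:
    @pytest.mark.parametrize(
        "nu_n,nu_p,sd",
        [(0.5, 0.0, 0.316), (0.5, 0.05, 0.392), (0.2, 0.0, 0.206), (0.9, 0.10, 0.532)],
    )
    def test_deletion_locus_published_cells(self, deletion_locus, nu_n, nu_p, sd):
        m = delta_moments(deletion_locus, ErrorRates(nu_p=nu_p, nu_n=nu_n))
        assert round(m.sd, 3) == sd

    def test_multiallelic_cell(self, multiallelic_locus):
        m = delta_moments(multiallelic_locus, ErrorRates(nu_p=0.05, nu_n=0.2))
        assert round(m.sd, 3) == 0.345

    def test_no_errors_no_variance(self, deletion_locus):
        m = delta_moments(deletion_locus, ErrorRates(0.0, 0.0))
        assert m.mean == 0.0 and m.sd == 0.0

    def test_symmetric_multiallelic_has_zero_mean(self, multiallelic_locus):
        m = delta_moments(multiallelic_locus, ErrorRates(nu_p=0.07, nu_n=0.3))
        assert m.mean == pytest.approx(0.0, abs=1e-15)

    @given(
        q=st.floats(0.01, 0.45),
        q2=st.floats(0.0, 0.45),
        nu_n=st.floats(0.0, 1.0),
        nu_p=st.floats(0.0, 1.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_closed_form_equals_joint_table_summation(self, q, q2, nu_n, nu_p):
        locus = make_locus_model("multiallelic", q, q2)
        rates = ErrorRates(nu_p=nu_p, nu_n=nu_n)
        closed = delta_moments(locus, rates)
        direct = delta_moments_from_joint(joint_call_distribution(locus, rates))
        assert closed.mean == pytest.approx(direct.mean, abs=1e-12)
        assert closed.variance == pytest.approx(direct.variance, abs=1e-12)

    def test_sd_monotone_in_both_rates(self, deletion_locus):
        grid = np.linspace(0.0, 0.9, 10)
        for nu_p in (0.0, 0.05, 0.1):
            sds = [delta_moments(deletion_locus, ErrorRates(nu_p, nn)).sd for nn in grid]
            assert np.all(np.diff(sds) >= -1e-12)
        for nu_n in (0.0, 0.3, 0.8):
            sds = [delta_moments(deletion_locus, ErrorRates(np_, nu_n)).sd for np_ in grid / 2]
            assert np.all(np.diff(sds) >= -1e-12)

    def test_deletion_and_duplication_share_variance(self, deletion_locus, duplication_locus):
        rates = ErrorRates(nu_p=0.08, nu_n=0.4)
        mdel = delta_moments(deletion_locus, rates)
        mdup = delta_moments(duplication_locus, rates)
        assert mdel.variance == pytest.approx(mdup.variance, abs=1e-12)
        assert mdel.mean == pytest.approx(-mdup.mean, abs=1e-12)  # sign-flipped error


class TestSdDeltaTable:
    def test_full_deletion_grid(self, deletion_locus):
        expected = np.array(
            [
                [0.000, 0.212, 0.294],
                [0.206, 0.301, 0.368],
                [0.316, 0.392, 0.451],
                [0.367, 0.438, 0.495],
                [0.407, 0.475, 0.532],
            ]
        )
        table = sd_delta_table(deletion_locus, [0, 0.2, 0.5, 0.7, 0.9], [0, 0.05, 0.10])
        assert np.array_equal(table.to_numpy(), expected)

    def test_full_multiallelic_grid(self, multiallelic_locus):
        expected = np.array(
            [
                [0.000, 0.197, 0.279],
                [0.283, 0.345, 0.397],
                [0.447, 0.489, 0.527],
                [0.529, 0.565, 0.598],
                [0.600, 0.632, 0.662],
            ]
        )
        table = sd_delta_table(multiallelic_locus, [0, 0.2, 0.5, 0.7, 0.9], [0, 0.05, 0.10])
        assert np.array_equal(table.to_numpy(), expected)

    def test_single_zero_cell(self, deletion_locus):
        table = sd_delta_table(deletion_locus, [0.0], [0.0])
        assert table.shape == (1, 1) and table.iloc[0, 0] == 0.0


class TestEquivalenceContour:
    def test_multiallelic_intercept_at_zero_false_positive(self, multiallelic_locus):
        # Var = nu_n * S2 with S2 = 0.4, so nu_n = 0.0225 / 0.4 at nu_p = 0
        pairs = equivalence_contour(multiallelic_locus, 0.15)
        # S1 = 0, so the contour ends where nu_n alone reaches the target
        nu_n_end, nu_p_end = max(pairs)
        assert nu_n_end == pytest.approx(0.05625, abs=1e-3)
        assert nu_p_end == pytest.approx(0.0, abs=1e-3)

    def test_deletion_intercept_at_zero_false_negative(self, deletion_locus):
        pairs = equivalence_contour(deletion_locus, 0.15)
        assert pairs[0][0] == 0.0
        assert pairs[0][1] == pytest.approx(0.024453, abs=1e-5)

    def test_contour_points_hit_target_variance(self, deletion_locus):
        for nu_n, nu_p in equivalence_contour(deletion_locus, 0.15)[::100]:
            m = delta_moments(deletion_locus, ErrorRates(nu_p=nu_p, nu_n=nu_n))
            assert m.variance == pytest.approx(0.15**2, abs=1e-9)

    def test_zero_target_only_origin(self, deletion_locus):
        pairs = equivalence_contour(deletion_locus, 0.0)
        assert pairs == [(0.0, 0.0)]


class TestSampleObservedCalls:
    def test_no_errors_identity(self, multiallelic_locus, rng):
        x = rng.choice(5, size=1000, p=multiallelic_locus.g)
        out = sample_observed_calls(x, multiallelic_locus, ErrorRates(0.0, 0.0), rng)
        assert np.array_equal(out, x)

    def test_total_false_negatives_collapse_to_reference(self, deletion_locus, rng):
        x = rng.choice(5, size=1000, p=deletion_locus.g)
        out = sample_observed_calls(x, deletion_locus, ErrorRates(nu_p=0.0, nu_n=1.0), rng)
        assert np.all(out == 2)

    def test_empirical_moments_match_closed_form(self, deletion_locus, rng):
        rates = ErrorRates(nu_p=0.05, nu_n=0.5)
        n = 10**6
        x = rng.choice(5, size=n, p=deletion_locus.g)
        delta = sample_observed_calls(x, deletion_locus, rates, rng) - x
        m = delta_moments(deletion_locus, rates)
        se_mean = m.sd / np.sqrt(n)
        assert delta.mean() == pytest.approx(m.mean, abs=3 * se_mean)
        # se of a sample sd is roughly sd / sqrt(2n) for near-Gaussian tails;
        # Delta is discrete so use a generous 4th-moment-free bound
        assert delta.std() == pytest.approx(m.sd, rel=0.01)

    def test_invalid_states_rejected(self, deletion_locus, rng):
        with pytest.raises(ValueError):
            sample_observed_calls(np.array([5]), deletion_locus, ErrorRates(0, 0), rng)
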