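"""Unit and property tests for the core deterministic recursion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from vaxculture import (
    IterationSettings,
    ObliqueFunctions,
    PhenotypeDistribution,
    SelectionFunction,
    TransmissionParameters,
    iterate,
    oblique_step,
    pair_subscript,
    selection_step,
    step,
    vaccination_probability,
    vertical_step,
)

from conftest import brute_force_generation, random_distribution, random_params

unit_floats = st.floats(0.0, 1.0, allow_nan=False)


def freq_vectors():
    return st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4).map(
        lambda f: PhenotypeDistribution.from_array(f, renormalize=True)
    )


def prob_vectors():
    return st.lists(unit_floats, min_size=4, max_size=4).map(tuple)


class TestPairSubscript:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [("+", "+", 3), ("-", "-", 0), ("-", "+", 1), ("+", "-", 2)],
    )
    def test_ordered_pair_convention(self, p1, p2, expected):
        assert pair_subscript(p1, p2) == expected

    def test_unicode_minus_accepted(self):
        assert pair_subscript("−", "+") == 1

    def test_invalid_trait_rejected(self):
        with pytest.raises(ValueError):
            pair_subscript("x", "+")


class TestVaccinationProbability:
    @pytest.mark.parametrize(
        "b, c, expected",
        [
            (0.99, 0.99, 0.98505),  # homogeneous confident & vaccinated couple
            (0.5, 0.5, 0.375),  # mixed-pair influence values
            (1.0, 1.0, 1.0),
            (0.7, 0.0, 0.0),
        ],
    )
    def test_formula(self, b, c, expected):
        assert vaccination_probability(b, c) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("b, c", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, b, c):
        with pytest.raises(ValueError):
            vaccination_probability(b, c)

    @given(unit_floats, unit_floats)
    def test_always_a_probability(self, b, c):
        assert 0.0 <= vaccination_probability(b, c) <= 1.0


class TestVerticalStep:
    def test_monomorphic_confident_vaccinated(self, baseline_params):
        """A V+A+ population reproduces through the single (m=3, n=3) pair."""
        dist = PhenotypeDistribution(1.0, 0.0, 0.0, 0.0)
        out = vertical_step(dist, baseline_params)
        B33, C3 = 0.98505, 0.99
        assert out.freq_VpAp == pytest.approx(B33 * C3, abs=1e-12)
        assert out.freq_VpAm == pytest.approx(B33 * (1 - C3), abs=1e-12)
        assert out.freq_VmAp == pytest.approx((1 - B33) * C3, abs=1e-12)
        assert out.freq_VmAm == pytest.approx((1 - B33) * (1 - C3), abs=1e-12)

    def test_monomorphic_hesitant_unvaccinated(self, baseline_params):
        """A V-A- population vaccinates at B00 = 0.01 * 1.01 / 2."""
        dist = PhenotypeDistribution(0.0, 0.0, 0.0, 1.0)
        out = vertical_step(dist, baseline_params)
        assert out.coverage == pytest.approx(0.00505, abs=1e-12)

    @given(freq_vectors(), st.integers(0, 2**31 - 1))
    @hyp_settings(max_examples=50, deadline=None)
    def test_mass_conserved(self, dist, seed):
        params = random_params(np.random.default_rng(seed))
        out = vertical_step(dist, params)
        assert out.as_array().sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(out.as_array() >= 0)

    def test_parental_symmetry_under_symmetric_baseline(self, baseline_params, initial_state):
        """With b1=b2, c1=c2, C1=C2, swapping parent roles changes nothing.

        Swapping roles maps subscript 1 <-> 2; under the symmetric baseline
        the ordered-pair result must equal itself with parents relabelled,
        which we probe by swapping the mixed-pair entries explicitly.
        """
        swapped = TransmissionParameters(
            C=(baseline_params.C[0], baseline_params.C[2], baseline_params.C[1], baseline_params.C[3]),
            b=(baseline_params.b[0], baseline_params.b[2], baseline_params.b[1], baseline_params.b[3]),
            c=(baseline_params.c[0], baseline_params.c[2], baseline_params.c[1], baseline_params.c[3]),
        )
        a = vertical_step(initial_state, baseline_params).as_array()
        b = vertical_step(initial_state, swapped).as_array()
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_enumeration_order_invariance(self, initial_state):
        """The ordered-pair sum is independent of enumeration order.

        Checked against the loop-wise oracle run with a shuffled pair order
        (commutativity of the sum), under asymmetric parameters.
        """
        rng = np.random.default_rng(7)
        params = random_params(rng)
        out = vertical_step(initial_state, params).as_array()

        freqs = initial_state.as_array()
        from conftest import PHENOTYPE_TRAITS

        pairs = [(i, j) for i in range(4) for j in range(4)]
        rng.shuffle(pairs)
        acc = np.zeros(4)
        for i, j in pairs:
            V1, A1 = PHENOTYPE_TRAITS[i]
            V2, A2 = PHENOTYPE_TRAITS[j]
            m, n = 2 * V1 + V2, 2 * A1 + A2
            B = params.c[n] * (1 + params.b[m]) / 2
            acc += freqs[i] * freqs[j] * np.array(
                [B * params.C[n], B * (1 - params.C[n]),
                 (1 - B) * params.C[n], (1 - B) * (1 - params.C[n])]
            )
        np.testing.assert_allclose(out, acc / acc.sum(), atol=1e-12)


class TestSelectionStep:
    def test_sigma_zero_is_identity(self, initial_state):
        out = selection_step(initial_state, 0.0)
        np.testing.assert_allclose(out.as_array(), initial_state.as_array(), atol=1e-15)

    def test_coverage_update_formula(self):
        """Coverage v maps to v(1+s) / (1 + s v)."""
        dist = PhenotypeDistribution(0.3, 0.2, 0.4, 0.1)
        out = selection_step(dist, 0.1)
        assert out.coverage == pytest.approx(0.55 / 1.05, abs=1e-12)

    def test_full_coverage_is_fixed_point(self):
        dist = PhenotypeDistribution(0.6, 0.4, 0.0, 0.0)
        out = selection_step(dist, -0.5)
        assert out.coverage == pytest.approx(1.0, abs=1e-12)

    def test_within_class_ratios_preserved(self):
        dist = PhenotypeDistribution(0.3, 0.2, 0.4, 0.1)
        out = selection_step(dist, 0.07)
        assert out.freq_VpAp / out.freq_VpAm == pytest.approx(1.5, abs=1e-9)
        assert out.freq_VmAp / out.freq_VmAm == pytest.approx(4.0, abs=1e-9)

    def test_lethal_sigma_rejected(self, initial_state):
        with pytest.raises(ValueError):
            selection_step(initial_state, -1.0)

    def test_lethal_sigma_allowed_without_vaccinated_mass(self):
        dist = PhenotypeDistribution(0.0, 0.0, 0.7, 0.3)
        out = selection_step(dist, -1.0)
        np.testing.assert_allclose(out.as_array(), dist.as_array(), atol=1e-15)


class TestObliqueStep:
    def test_no_switching_is_identity(self, initial_state):
        out = oblique_step(initial_state, 0.0, 0.0)
        np.testing.assert_allclose(out.as_array(), initial_state.as_array(), atol=1e-15)

    def test_single_flow_from_confident(self):
        dist = PhenotypeDistribution(0.7, 0.0, 0.3, 0.0)
        out = oblique_step(dist, 0.0, 0.25)
        assert out.freq_VpAm == pytest.approx(0.7 * 0.25, abs=1e-15)
        assert out.freq_VmAm == pytest.approx(0.3 * 0.25, abs=1e-15)

    @given(freq_vectors(), unit_floats, unit_floats)
    @hyp_settings(max_examples=100, deadline=None)
    def test_coverage_conserved_exactly(self, dist, p_hc, p_ch):
        out = oblique_step(dist, p_hc, p_ch)
        # attitude flips move mass within vaccination classes only
        assert out.coverage == dist.coverage
        assert out.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_rejected(self, initial_state):
        with pytest.raises(ValueError):
            oblique_step(initial_state, 1.5, 0.0)


class TestStep:
    def test_reduces_to_vertical_step_without_selection_or_oblique(
        self, baseline_params, initial_state
    ):
        sel = SelectionFunction(family="constant", sigma_max=0.0)
        new, sigma = step(initial_state, baseline_params, sel, ObliqueFunctions.none())
        assert sigma == 0.0
        expected = vertical_step(initial_state, baseline_params)
        np.testing.assert_allclose(new.as_array(), expected.as_array(), atol=1e-15)

    def test_valid_output_at_baseline(self, baseline_params, initial_state,
                                      default_selection, default_oblique):
        new, sigma = step(initial_state, baseline_params, default_selection, default_oblique)
        assert 0.0 <= new.coverage <= 1.0
        assert abs(sigma) <= default_selection.sigma_max

    def test_sigma_evaluated_at_parental_coverage(self, baseline_params, initial_state):
        """The applied sigma must reflect the generation entering the step."""
        seen = []

        class Probe:
            sigma_max = 0.1

            def __call__(self, v):
                seen.append(v)
                return 0.0

        step(initial_state, baseline_params, Probe(), ObliqueFunctions.none())
        assert seen == [pytest.approx(initial_state.coverage)]

    def test_agrees_with_brute_force_oracle(self):
        """Full generation matches the independent 16-pair enumeration.

        100 random (state, parameters, sigma, transition-probability) draws,
        agreement to 1e-12 on every phenotype.
        """
        rng = np.random.default_rng(12345)
        for _ in range(100):
            dist = random_distribution(rng)
            params = random_params(rng)
            sigma = rng.uniform(-0.5, 0.5)
            p_hc, p_ch = rng.random(2)

            class Fixed:
                def __init__(self, s):
                    self.s = s

                def __call__(self, v):
                    return self.s

            class FixedOblique:
                def hesitant_to_confident(self, v):
                    return p_hc

                def confident_to_hesitant(self, v):
                    return p_ch

            new, applied = step(dist, params, Fixed(sigma), FixedOblique())
            expected = brute_force_generation(
                dist.as_array().tolist(), params.C, params.b, params.c, sigma, p_hc, p_ch
            )
            assert applied == sigma
            np.testing.assert_allclose(new.as_array(), expected, atol=1e-12)


class TestIterate:
    def test_fixed_point_flagged_immediately(self, baseline_params, default_selection,
                                             default_oblique, settings_100):
        """Feeding an equilibrium back in re-detects equilibrium at once."""
        init = PhenotypeDistribution(0.81, 0.10, 0.07, 0.02)
        eq = iterate(init, baseline_params, default_selection, default_oblique,
                     IterationSettings(max_iterations=2000, equilibrium_tolerance=1e-14)).final
        again = iterate(eq, baseline_params, default_selection, default_oblique, settings_100)
        assert again.reached_equilibrium
        assert again.equilibrium_iteration == 1
        assert again.final.max_abs_difference(eq) < 1e-10

    def test_baseline_equilibrium_phenotype_ranking(self, baseline_params, initial_state,
                                                    default_selection, default_oblique,
                                                    settings_100):
        """At baseline the extremes dominate: V+A+ and V-A- are the two most
        abundant phenotypes at equilibrium."""
        traj = iterate(initial_state, baseline_params, default_selection,
                       default_oblique, settings_100)
        order = np.argsort(traj.final.as_array())[::-1]
        assert set(order[:2]) == {0, 3}  # VpAp and VmAm

    def test_convergence_100_vs_1000_iterations(self, baseline_params, initial_state,
                                                default_selection, default_oblique):
        t100 = iterate(initial_state, baseline_params, default_selection, default_oblique,
                       IterationSettings(max_iterations=100, equilibrium_tolerance=1e-300))
        t1000 = iterate(initial_state, baseline_params, default_selection, default_oblique,
                        IterationSettings(max_iterations=1000, equilibrium_tolerance=1e-300))
        assert abs(t100.final.coverage - t1000.final.coverage) < 1e-6

    def test_trajectory_bookkeeping(self, baseline_params, initial_state,
                                    default_selection, default_oblique):
        traj = iterate(initial_state, baseline_params, default_selection, default_oblique,
                       IterationSettings(max_iterations=10, equilibrium_tolerance=1e-300))
        assert len(traj.states) == 11
        assert len(traj.sigma_series) == traj.n_iterations == 10
        assert not traj.reached_equilibrium
        for s in traj.states:
            assert s.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_equilibrium_coverage_monotone_in_attitude_influence(
        self, baseline_params, initial_state, default_selection, default_oblique, settings_100
    ):
        """Raising any attitude-influence entry c_n cannot lower equilibrium coverage."""
        base_cov = iterate(initial_state, baseline_params, default_selection,
                           default_oblique, settings_100).final.coverage
        for idx in range(4):
            prev = base_cov if baseline_params.c[idx] <= 0.2 else None
            for value in (0.2, 0.6, 0.95):
                c = list(baseline_params.c)
                c[idx] = value
                cov = iterate(initial_state, baseline_params.replace(c=tuple(c)),
                              default_selection, default_oblique, settings_100).final.coverage
                if prev is not None:
                    assert cov >= prev - 1e-9
                prev = cov


class TestPhenotypeDistribution:
    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeDistribution(0.5, 0.5, 0.5, 0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeDistribution(-0.1, 0.5, 0.5, 0.1)

    def test_marginals(self, initial_state):
        assert initial_state.coverage == pytest.approx(0.91)
        assert initial_state.confidence == pytest.approx(0.88)

    def test_transmission_parameter_range_checks(self):
        with pytest.raises(ValueError):
            TransmissionParameters(C=(0, 0, 0, 1.5), b=(0,) * 4, c=(0,) * 4)
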