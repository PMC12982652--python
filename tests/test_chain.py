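"""Exact chain quantities: normalization, stationarity, entropy rates,
conditioning, mixing and recurrence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import entrochain as ec
from entrochain.chain import _stationary_linear, _stationary_power
from entrochain.errors import (
    AllZeroRowError,
    DimensionMismatchError,
    MixingCapReachedError,
    NegativeEntryError,
    NonSquareMatrixError,
    ReducibleChainError,
)
from conftest import random_stochastic


class TestValidateAndNormalize:
    def test_row_division_and_report(self):
        ch = ec.validate_and_normalize([[1, 1], [3, 1]], ["x", "y"], warn_tol=10)
        np.testing.assert_allclose(ch.P, [[0.5, 0.5], [0.75, 0.25]])
        assert ch.normalization_report == {"x": 2.0, "y": 4.0}

    def test_already_stochastic_identity_unchanged(self, recwarn):
        ch = ec.validate_and_normalize(np.eye(3), ["a", "b", "c"])
        np.testing.assert_array_equal(ch.P, np.eye(3))
        assert not [w for w in recwarn if issubclass(w.category, UserWarning)]

    def test_warns_on_deviating_rows(self):
        with pytest.warns(UserWarning, match="row y sums to 1.1"):
            ec.validate_and_normalize([[1, 0], [0.55, 0.55]], ["x", "y"])

    @pytest.mark.parametrize(
        "raw, err",
        [
            ([[1, 0, 0], [0, 1, 0]], NonSquareMatrixError),
            ([[1, -0.1], [0, 1]], NegativeEntryError),
            ([[1, 0], [0, 0]], AllZeroRowError),
        ],
    )
    def test_distinct_errors(self, raw, err):
        with pytest.raises(err):
            ec.validate_and_normalize(raw, list("ab" if len(raw) < 3 else "abc"))

    @given(
        M=arrays(float, (4, 4), elements=st.floats(0.01, 50)),
        tol=st.floats(0.001, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_normalization_is_row_stochastic(self, M, tol):
        with pytest.warns(UserWarning):
            ch = ec.validate_and_normalize(M, list("wxyz"), warn_tol=1e-12)
        np.testing.assert_allclose(ch.P.sum(1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            list(ch.normalization_report.values()), M.sum(1), rtol=1e-12
        )


class TestStationary:
    def test_symmetric_two_state(self, fair_coin_chain):
        pi = ec.stationary_distribution(fair_coin_chain)
        np.testing.assert_allclose(pi.values, [0.5, 0.5], atol=1e-12)

    def test_fixed_point_residual(self, fixture_chain):
        pi = ec.stationary_distribution(fixture_chain)
        assert np.abs(pi.values @ fixture_chain.P - pi.values).sum() < 1e-9

    def test_matches_long_run_frequencies(self, rng):
        """Analytic pi vs visit frequencies of a 10^6-step simulation, 3 SE.

        The SE of an occupancy frequency under autocorrelation is estimated
        by batch means (1000 batches of 1000 days)."""
        P = random_stochastic(3, rng)
        ch = ec.validate_and_normalize(P, ["a", "b", "c"])
        pi = ec.stationary_distribution(ch)
        traj = ec.simulate(ch, 1_000_000, seed=99)
        for lab, p in pi.as_dict().items():
            hits = (traj.micro == lab).astype(float)
            batches = hits.reshape(1000, 1000).mean(axis=1)
            se = batches.std(ddof=1) / np.sqrt(len(batches))
            assert abs(hits.mean() - p) < 3 * se

    def test_reducible_chain_names_classes(self):
        P = [[1, 0], [0, 1]]
        ch = ec.validate_and_normalize(P, ["a", "b"])
        with pytest.raises(ReducibleChainError) as ei:
            ec.stationary_distribution(ch)
        assert sorted(map(sorted, ei.value.classes)) == [["a"], ["b"]]

    def test_linear_and_power_methods_agree(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            P = random_stochastic(n, rng)
            assert np.abs(_stationary_linear(P) - _stationary_power(P)).sum() < 1e-9


class TestMacroMarginal:
    def test_uniform_blocks(self, fixture_chain):
        space = fixture_chain.space
        pi = ec.StationaryDistribution(
            np.full(20, 1 / 20), space.flat_labels, "flat"
        )
        mm = ec.macro_marginal(pi, space)
        np.testing.assert_allclose(mm.values, 0.2)

    def test_point_mass(self, fixture_chain):
        space = fixture_chain.space
        v = np.zeros(20)
        v[space.flat_index("D", "R")] = 1.0
        mm = ec.macro_marginal(
            ec.StationaryDistribution(v, space.flat_labels, "flat"), space
        )
        assert mm["D"] == 1.0

    def test_level_mismatch(self, fixture_chain):
        mm = ec.macro_marginal(
            ec.stationary_distribution(fixture_chain), fixture_chain.space
        )
        with pytest.raises(DimensionMismatchError):
            ec.macro_marginal(mm, fixture_chain.space)

    def test_modal_macro_of_reference_chain(self, fixture_chain):
        """The stable regime dominates its own long-run occupancy ranking
        relative to acute/persistent; the printed source claims D is modal
        outright, which the as-printed matrix does not reproduce (see the
        normalization report)."""
        mm = ec.macro_marginal(
            ec.stationary_distribution(fixture_chain), fixture_chain.space
        )
        d = mm.as_dict()
        assert d["D"] > d["A"] and d["D"] > d["B"] and d["D"] > d["C"]


class TestEntropyRate:
    def test_fair_coin_is_one_bit(self, fair_coin_chain):
        assert ec.entropy_rate(fair_coin_chain) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_cycle_is_zero(self, cycle_chain):
        assert ec.entropy_rate(cycle_chain) == pytest.approx(0.0, abs=1e-12)

    def test_bounds_on_random_chains(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            ch = ec.validate_and_normalize(
                random_stochastic(n, rng), [str(i) for i in range(n)]
            )
            assert 0 <= ec.entropy_rate(ch) <= np.log2(n) + 1e-12

    def test_dimension_mismatch(self, fixture_chain, fair_coin_chain):
        pi = ec.stationary_distribution(fair_coin_chain)
        with pytest.raises(DimensionMismatchError):
            ec.entropy_rate(fixture_chain, pi)


class TestConditionalMicroChain:
    def test_no_leak_block_unchanged(self, uniform_block_chain):
        # with cross-macro mass removed the renormalized rows are uniform
        P_t, pi_t = ec.conditional_micro_chain(uniform_block_chain, "X")
        np.testing.assert_allclose(P_t, 0.25, atol=1e-12)
        np.testing.assert_allclose(pi_t.values, 0.25, atol=1e-12)

    def test_reference_row_renormalization(self, fixture_chain):
        row = np.array([0.6591, 0.1142, 0.0422, 0.0235])
        P_t, _ = ec.conditional_micro_chain(fixture_chain, "D")
        np.testing.assert_allclose(P_t[0], row / row.sum(), atol=1e-12)

    def test_two_micro_closed_form(self):
        a, b, c, d = 0.30, 0.10, 0.05, 0.45
        space = ec.StateSpace(("M", "O"), (("x", "y"), ("z",)))
        P = np.array([
            [a, b, 0.60], [c, d, 0.50], [0.2, 0.2, 0.6],
        ])
        ch = ec.validate_and_normalize(P, space)
        _, pi_t = ec.conditional_micro_chain(ch, "M")
        # renormalized 2x2 block [[a,b],[c,d]]/rows has stationary
        # [c', b'] / (b' + c') with b' = b/(a+b), c' = c/(c+d)
        bb, cc = b / (a + b), c / (c + d)
        np.testing.assert_allclose(
            pi_t.values, [cc / (bb + cc), bb / (bb + cc)], atol=1e-9
        )

    def test_unreachable_micro_state_errors(self):
        space = ec.StateSpace(("M", "O"), (("x", "y"), ("z",)))
        P = [[0, 0, 1], [0.25, 0.25, 0.5], [0.2, 0.2, 0.6]]
        ch = ec.validate_and_normalize(P, space)
        with pytest.raises(AllZeroRowError, match="x"):
            ec.conditional_micro_chain(ch, "M")

    def test_global_pi_source_differs_but_is_valid(self, fixture_chain):
        _, pi_block = ec.conditional_micro_chain(fixture_chain, "A")
        _, pi_glob = ec.conditional_micro_chain(fixture_chain, "A",
                                                pi_source="global")
        assert pi_glob.values.sum() == pytest.approx(1.0)
        assert not np.allclose(pi_block.values, pi_glob.values, atol=1e-4)


class TestMacroCentricEntropyRate:
    def test_deterministic_block_is_zero(self):
        space = ec.StateSpace(("M", "O"), (("x", "y"), ("z",)))
        P = [[0, 0.9, 0.1], [0.9, 0, 0.1], [0.2, 0.2, 0.6]]
        ch = ec.validate_and_normalize(P, space)
        assert ec.macro_centric_entropy_rate(ch, "M") == pytest.approx(0.0, abs=1e-12)

    def test_uniform_block_is_two_bits(self, uniform_block_chain):
        assert ec.macro_centric_entropy_rate(
            uniform_block_chain, "X"
        ) == pytest.approx(2.0, abs=1e-12)

    def test_bounds_for_all_macros(self, fixture_chain):
        for m in fixture_chain.space.macro_labels:
            h = ec.macro_centric_entropy_rate(fixture_chain, m)
            assert 0 <= h <= 2.0

    def test_block_diagonal_equals_standalone_block(self, rng):
        """With zero cross-macro mass, conditioning changes nothing."""
        B = random_stochastic(4, rng)
        space = ec.StateSpace.uniform(("X", "Y"), ("R", "W", "N", "F"))
        P = np.zeros((8, 8))
        P[:4, :4] = B
        P[4:, 4:] = random_stochastic(4, rng)
        ch = ec.validate_and_normalize(P, space)
        standalone = ec.validate_and_normalize(B, ["R", "W", "N", "F"])
        assert ec.macro_centric_entropy_rate(ch, "X") == pytest.approx(
            ec.entropy_rate(standalone), abs=1e-12
        )


class TestMixingTime:
    def test_rank_one_chain_mixes_in_one_step(self):
        pi = np.array([0.2, 0.3, 0.5])
        ch = ec.validate_and_normalize(np.tile(pi, (3, 1)), ["a", "b", "c"])
        assert ec.mixing_time(ch) == 1

    def test_two_state_closed_form(self, rng):
        """TV decay from start i is max(pi) * |1-a-b|^t; compare exactly."""
        for _ in range(10):
            a, b = rng.uniform(0.05, 0.95, 2)
            ch = ec.validate_and_normalize([[1 - a, a], [b, 1 - b]], ["u", "v"])
            lam = abs(1 - a - b)
            pi_max = max(a, b) / (a + b)
            eps = 0.1
            if lam == 0:
                expected = 1
            else:
                t = 1
                while pi_max * lam**t > eps:
                    t += 1
                expected = t
            assert ec.mixing_time(ch, epsilon=eps) == expected

    def test_monotone_in_epsilon(self, fixture_chain):
        times = [ec.mixing_time(fixture_chain, e) for e in (0.05, 0.1, 0.25, 0.4)]
        assert times == sorted(times, reverse=True)
        assert all(isinstance(t, int) and t >= 1 for t in times)

    def test_periodic_chain_hits_cap(self, cycle_chain):
        with pytest.raises(MixingCapReachedError):
            ec.mixing_time(cycle_chain, epsilon=0.1, cap=500)

    def test_epsilon_domain(self, fair_coin_chain):
        with pytest.raises(ValueError):
            ec.mixing_time(fair_coin_chain, epsilon=1.5)


class TestMeanRecurrenceTime:
    def test_uniform_four_states(self):
        pi = ec.StationaryDistribution([0.25] * 4, list("abcd"), "flat")
        assert all(ec.mean_recurrence_time(pi, s) == 4.0 for s in "abcd")

    def test_reciprocal_of_reported_occupancy(self):
        pi = ec.StationaryDistribution(
            [0.0532, 0.0338, 0.1249, 0.5959, 0.1922], list("ABCDE"), "macro"
        )
        assert ec.mean_recurrence_time(pi, "D") == pytest.approx(1.678, abs=1e-3)

    def test_zero_mass_errors(self):
        pi = ec.StationaryDistribution([1.0, 0.0], ["a", "b"], "flat")
        with pytest.raises(ValueError):
            ec.mean_recurrence_time(pi, "b")

    def test_matches_empirical_return_times(self, fixture_chain, long_run):
        """Kac's formula vs mean return time in the shared 10^6-day run."""
        pi = ec.stationary_distribution(fixture_chain)
        lab = "ER"  # high-occupancy state of the as-printed chain
        visits = np.nonzero(long_run.flat_labels == lab)[0]
        gaps = np.diff(visits)
        emp, se = gaps.mean(), gaps.std(ddof=1) / np.sqrt(len(gaps))
        assert abs(ec.mean_recurrence_time(pi, lab) - emp) < 3 * se


def test_metrics_report_is_json_serializable(fixture_chain):
    import json

    rep = ec.metrics_report(fixture_chain)
    assert set(rep["macro_centric_entropy_rates"]) == set("ABCDE")
    assert rep["units"] == "bits/day"
    json.dumps(rep)
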