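"""Drift analysis and truncated-chain numerics."""

import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import genomesize as gs
from genomesize.stationarity import TruncatedChain, expected_scaled_jump

LOG2 = math.log(2.0)


def _brute_force_jump(s, etype, indel, rearr, f):
    """Oracle: explicit sum over the full one-mutation transition law."""
    if etype == "small_insertion":
        return sum(p * (f(s + k) - f(s)) for k, p in enumerate(indel.p_ins, 1))
    if etype == "small_deletion":
        return sum(p * (f(max(0, s - k)) - f(s)) for k, p in enumerate(indel.p_sdel, 1))
    if rearr.kind == "uniform":
        sizes = range(1, s + 1)
        weights = [1.0 / s] * s
    else:  # empirical table truncated at s
        pairs = [(int(x), w) for x, w in zip(rearr.sizes, rearr.weights) if x <= s]
        total = sum(w for _, w in pairs)
        sizes = [x for x, _ in pairs]
        weights = [w / total for _, w in pairs]
    sign = -1 if etype == "large_deletion" else 1
    return sum(w * (f(s + sign * x) - f(s)) for x, w in zip(sizes, weights))


class TestExpectedScaledJump:
    def test_uniform_deletion_small_sizes(self, indel40, uniform_rearr):
        flog = lambda x: math.log(x) if x > 0 else 0.0
        assert expected_scaled_jump(1, "large_deletion", indel40, uniform_rearr) == 0.0
        assert expected_scaled_jump(
            2, "large_deletion", indel40, uniform_rearr
        ) == pytest.approx(-LOG2, rel=1e-12)
        assert expected_scaled_jump(
            2, "large_deletion", indel40, uniform_rearr
        ) == pytest.approx(_brute_force_jump(2, "large_deletion", indel40, uniform_rearr, flog))

    @pytest.mark.parametrize("s", [5, 17, 120])
    @pytest.mark.parametrize("etype", list(gs.EVENT_TYPES))
    @pytest.mark.parametrize("scaling", ["log", "identity"])
    def test_matches_brute_force(self, s, etype, scaling, indel40, uniform_rearr):
        if scaling == "log":
            f = lambda x: math.log(x) if x > 0 else 0.0
        else:
            f = float
        got = expected_scaled_jump(s, etype, indel40, uniform_rearr, scaling)
        assert got == pytest.approx(
            _brute_force_jump(s, etype, indel40, uniform_rearr, f), abs=1e-10
        )

    def test_empirical_table_matches_brute_force(self, indel40):
        rearr = gs.RearrangementSizeModel.empirical([2, 5, 11], [1.0, 2.0, 1.0])
        flog = lambda x: math.log(x) if x > 0 else 0.0
        for s in (6, 20):
            got = expected_scaled_jump(s, "duplication", indel40, rearr, "log")
            assert got == pytest.approx(
                _brute_force_jump(s, "duplication", indel40, rearr, flog), abs=1e-12
            )

    def test_asymptotic_uniform_log_limits(self, indel40, uniform_rearr):
        s = 10**9
        assert expected_scaled_jump(s, "large_deletion", indel40, uniform_rearr) == (
            pytest.approx(-1.0, abs=1e-6)
        )
        assert expected_scaled_jump(s, "duplication", indel40, uniform_rearr) == (
            pytest.approx(2 * LOG2 - 1, abs=1e-6)
        )
        assert abs(expected_scaled_jump(s, "small_insertion", indel40, uniform_rearr)) < 1e-6

    def test_boundary_state_refused(self, indel40, uniform_rearr):
        with pytest.raises(ValueError):
            expected_scaled_jump(0, "large_deletion", indel40, uniform_rearr)


class TestAsymptoticDeltas:
    def test_uniform_log_plateaus(self, indel40, uniform_rearr):
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "log")
        assert d.all_converged
        assert d.deltas["large_deletion"] == pytest.approx(-1.0, abs=1e-5)
        assert d.deltas["duplication"] == pytest.approx(2 * LOG2 - 1, abs=1e-5)
        assert abs(d.deltas["small_insertion"]) < 1e-5
        assert abs(d.deltas["small_deletion"]) < 1e-5
        # sign structure: losses down, gains up
        assert d.deltas["large_deletion"] <= 0 <= d.deltas["duplication"]

    def test_lognormal_identity_plateaus_at_complete_mean(self, indel40, lognormal_rearr):
        d = gs.estimate_asymptotic_deltas(indel40, lognormal_rearr, "identity")
        assert d.all_converged
        mean = gs.asymptotic_event_size()
        assert d.deltas["large_deletion"] == pytest.approx(-mean, rel=1e-3)
        assert d.deltas["duplication"] == pytest.approx(mean, rel=1e-3)
        # exact means of the indel law, not the rounded value 20
        assert d.deltas["small_insertion"] == 20.5
        assert d.deltas["small_deletion"] == -20.5

    def test_uniform_identity_never_plateaus(self, indel40, uniform_rearr):
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "identity")
        assert not d.converged["large_deletion"]
        assert not d.converged["duplication"]


class TestStationarityCondition:
    def test_bacterial_uniform_converges(self, bacterial_rates, indel40, uniform_rearr):
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "log")
        v = gs.stationarity_condition(bacterial_rates, d)
        assert v.verdict == "converges"
        expected = 3.778e-9 * ((2 * LOG2 - 1) - 1)  # ~ -2.32e-9
        assert v.net_drift == pytest.approx(expected, rel=1e-5)

    def test_bacterial_lognormal_is_inconclusive(
        self, bacterial_rates, indel40, lognormal_rearr
    ):
        d = gs.estimate_asymptotic_deltas(indel40, lognormal_rearr, "identity")
        v = gs.stationarity_condition(bacterial_rates, d)
        assert v.verdict == "inconclusive"
        assert v.net_drift == 0.0

    def test_balanced_rates_are_inconclusive(self, indel40, uniform_rearr):
        # mu_dup / mu_ldel exactly 1/(2 log 2 - 1) zeroes the net drift
        mu = 3.778e-9
        rates = gs.MutationRates(0, 0, mu, mu / (2 * LOG2 - 1))
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "log")
        v = gs.stationarity_condition(rates, d)
        assert v.verdict == "inconclusive"

    def test_growth_regime_not_guaranteed(self, indel40, uniform_rearr):
        rates = gs.MutationRates(0, 0, 1e-9, 1e-8)
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "log")
        assert gs.stationarity_condition(rates, d).verdict == "not_guaranteed"

    def test_unconverged_deltas_refuse_to_conclude(
        self, bacterial_rates, indel40, uniform_rearr
    ):
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "identity")
        assert gs.stationarity_condition(bacterial_rates, d).verdict == "inconclusive"

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        mu_ldel=st.floats(min_value=1e-10, max_value=1e-5),
        ratio=st.floats(min_value=0.1, max_value=10.0),
        mu_indel=st.floats(min_value=0.0, max_value=1e-5),
    )
    def test_generic_condition_reduces_to_uniform_inequality(
        self, mu_ldel, ratio, mu_indel
    ):
        """With f = log the drift balance and the closed inequality
        (2 log 2 - 1) mu_dup < mu_ldel agree on every rate draw."""
        rates = gs.MutationRates(mu_indel, mu_indel, mu_ldel, ratio * mu_ldel)
        indel = gs.IndelSizeModel.uniform(40)
        rearr = gs.RearrangementSizeModel.uniform()
        d = gs.estimate_asymptotic_deltas(indel, rearr, "log")
        v = gs.stationarity_condition(rates, d)
        if v.verdict == "converges":
            assert gs.uniform_shrinkage_condition(rates)
        elif v.verdict == "not_guaranteed":
            assert not gs.uniform_shrinkage_condition(rates)

    def test_net_drift_monotonic_in_rates(self, indel40, uniform_rearr):
        d = gs.estimate_asymptotic_deltas(indel40, uniform_rearr, "log")
        base = gs.MutationRates(1e-9, 1e-9, 2e-9, 1e-9)
        net = lambda r: gs.stationarity_condition(r, d).net_drift
        more_dup = gs.MutationRates(1e-9, 1e-9, 2e-9, 2e-9)
        more_del = gs.MutationRates(1e-9, 1e-9, 4e-9, 1e-9)
        assert net(more_dup) > net(base)
        assert net(more_del) < net(base)


class TestTruncatedChains:
    def test_m1_row_zero_structure(self, scaled_rates, uniform_rearr):
        indel = gs.IndelSizeModel.uniform(10)
        chain = gs.build_m1(60, scaled_rates, indel, uniform_rearr)
        row0 = chain.matrix[0].toarray().ravel()
        probs = scaled_rates.type_probabilities()
        # only insertions leave 0; everything else is self-mass
        assert row0[0] == pytest.approx(1 - probs[0], rel=1e-12)
        np.testing.assert_allclose(row0[1:11], probs[0] / 10, rtol=1e-12)
        assert row0[11:].sum() == 0

    def test_m1_rows_are_stochastic_with_leak(self, scaled_rates, lognormal_rearr):
        indel = gs.IndelSizeModel.uniform(10)
        small_ln = gs.RearrangementSizeModel.truncated_lognormal(3.0, 1.0)
        for rearr in (gs.RearrangementSizeModel.uniform(), small_ln):
            chain = gs.build_m1(80, scaled_rates, indel, rearr)
            stored = np.asarray(chain.matrix.sum(axis=1)).ravel()
            np.testing.assert_allclose(stored + chain.leaked_mass, 1.0, atol=1e-10)

    def test_m1_duplication_block_is_flat(self, scaled_rates, uniform_rearr):
        indel = gs.IndelSizeModel.uniform(10)
        chain = gs.build_m1(100, scaled_rates, indel, uniform_rearr)
        s = 30
        row = chain.matrix[s].toarray().ravel()
        w_dup = scaled_rates.type_probabilities()[3]
        np.testing.assert_allclose(row[s + 11 : 2 * s + 1], w_dup / s, rtol=1e-12)

    def test_mg_tends_to_identity_at_vanishing_rates(self, uniform_rearr):
        rates = gs.MutationRates(2e-9, 2e-9, 1e-9, 1e-9)
        indel = gs.IndelSizeModel.uniform(10)
        chain = gs.build_mg(40, rates, indel, uniform_rearr)
        diag = chain.matrix.diagonal()
        assert diag.min() > 1 - 1e-6

    def test_mg_row_matches_generation_simulation(self, scaled_rates, uniform_rearr):
        """A single M_G row agrees with Monte-Carlo one-generation outcomes
        (TV < 0.01 at n = 200,000)."""
        s_max, start, n = 150, 40, 200_000
        indel = gs.IndelSizeModel.uniform(10)
        chain = gs.build_mg(s_max, scaled_rates, indel, uniform_rearr)
        row = chain.matrix[start - 1].toarray().ravel()  # states begin at 1
        rng = np.random.default_rng(17)
        counts = np.zeros(s_max + 1)
        overflow = 0
        for _ in range(n):
            out = gs.one_generation(start, scaled_rates, indel, uniform_rearr, rng)
            if out.end_size <= s_max:
                counts[out.end_size] += 1
            else:
                overflow += 1
        empirical = counts[1:] / n
        tv = 0.5 * (np.abs(empirical - row).sum() + abs(overflow / n - chain.leaked_mass[start - 1]))
        assert tv < 0.01

    def test_stationary_two_state_closed_form(self):
        # balance equations: pi = (2/3, 1/3) for this kernel
        mat = sp.csr_matrix(np.array([[0.9, 0.1], [0.2, 0.8]]))
        chain = TruncatedChain(
            states=np.array([1, 2]), matrix=mat, leaked_mass=np.zeros(2), kind="MG"
        )
        pi, diag = gs.stationary_distribution(chain, tol=1e-13)
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-10)
        # power iteration increments decay geometrically
        l1 = diag["l1_increments"]
        assert l1[-1] < l1[0]

    def test_stationary_independent_of_start(self, scaled_rates, uniform_rearr):
        indel = gs.IndelSizeModel.uniform(5)
        chain = gs.build_mg(120, scaled_rates, indel, uniform_rearr)
        pi_a, _ = gs.stationary_distribution(chain)
        start = np.zeros(120)
        start[-1] = 1.0
        pi_b, _ = gs.stationary_distribution(chain, initial=start)
        assert 0.5 * np.abs(pi_a - pi_b).sum() < 1e-8

    def test_stationary_stable_under_window_growth(self, scaled_rates, uniform_rearr):
        indel = gs.IndelSizeModel.uniform(5)
        small = gs.build_mg(100, scaled_rates, indel, uniform_rearr)
        big = gs.build_mg(160, scaled_rates, indel, uniform_rearr)
        pi_small, _ = gs.stationary_distribution(small)
        pi_big, _ = gs.stationary_distribution(big)
        tv = 0.5 * np.abs(np.r_[pi_small, np.zeros(60)] - pi_big).sum()
        assert tv < 1e-3
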