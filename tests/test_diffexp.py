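"""Variance prior, moderated t, BH adjustment, calls, aggregation, counting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

from lfqde import (
    AnalysisConfig,
    VariancePrior,
    aggregate_cycles,
    bh_adjust,
    count_by_thresholds,
    fit_variance_prior,
    moderated_t,
    significance_call,
)

DESIGN = {"c1": "ctl", "c2": "ctl", "c3": "ctl", "t1": "trt", "t2": "trt", "t3": "trt"}


def bh_brute_force(p):
    """O(n^2) literal step-up definition."""
    p = np.asarray(p, float)
    n = len(p)
    q = np.empty(n)
    order = np.argsort(p, kind="stable")
    for pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * n / j
            for j in range(pos, n + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestFitVariancePrior:
    def test_equal_variances_give_unbounded_prior(self):
        prior = fit_variance_prior([2.0, 2.0, 2.0, 2.0], df=4)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.0)

    def test_parameter_recovery_from_scaled_f_variances(self):
        """s^2 ~ s0^2 F(d, d0) with d0=4, s0^2=1: recovery within 15% / 10%."""
        rng = np.random.default_rng(3)
        d0, s0_sq, d, n = 4.0, 1.0, 4, 5000
        sigma2 = s0_sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        prior = fit_variance_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_two_point_instance_against_independent_solver(self):
        """{1, e^2} at df=4: solve the two-point moment equations with an
        independent root finder and compare."""
        s2 = np.array([1.0, math.e**2])
        d = 4.0
        e = np.log(s2) - special.digamma(d / 2) + math.log(d / 2)
        evar = e.var(ddof=1)
        target = evar - special.polygamma(1, d / 2)
        assert target > 0
        half_d0 = optimize.brentq(lambda y: special.polygamma(1, y) - target, 1e-6, 1e6)
        want_d0 = 2 * half_d0
        want_s0 = math.exp(
            e.mean() + special.digamma(half_d0) - math.log(half_d0)
        )
        prior = fit_variance_prior(s2, d)
        assert prior.d0 == pytest.approx(want_d0, rel=1e-6)
        assert prior.s0_sq == pytest.approx(want_s0, rel=1e-6)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            fit_variance_prior([0.0, 0.0, 0.0], df=4)


class TestModeratedT:
    def _data(self, rng, n=100):
        return pd.DataFrame(
            rng.normal(20, 2, (n, 6)),
            index=[f"P{i}" for i in range(n)],
            columns=list(DESIGN),
        )

    def test_identical_group_means_give_zero_t(self):
        data = pd.DataFrame(
            [[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]], index=["P1"], columns=list(DESIGN)
        )
        res = moderated_t(data, DESIGN, VariancePrior(d0=4.0, s0_sq=1.0))
        assert res.loc["P1", "t"] == 0.0
        assert res.loc["P1", "p"] == 1.0

    def test_d0_to_zero_limit_is_ordinary_pooled_t(self):
        """With a vanishing prior the statistic and p equal the textbook
        pooled two-sample t (independent scipy computation)."""
        rng = np.random.default_rng(11)
        data = self._data(rng)
        res = moderated_t(data, DESIGN, VariancePrior(d0=1e-12, s0_sq=1.0))
        g1, g2 = list(DESIGN)[:3], list(DESIGN)[3:]
        t_ref, p_ref = sps.ttest_ind(
            data[g2].to_numpy().T, data[g1].to_numpy().T, equal_var=True
        )
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ref, rtol=1e-8)

    def test_unbounded_d0_is_closed_form_z(self):
        rng = np.random.default_rng(12)
        data = self._data(rng, n=50)
        s0_sq = 1.7
        res = moderated_t(data, DESIGN, VariancePrior(d0=math.inf, s0_sq=s0_sq))
        lfc = data.iloc[:, 3:].mean(axis=1) - data.iloc[:, :3].mean(axis=1)
        z = lfc / math.sqrt(s0_sq * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res["t"].to_numpy(), z, rtol=1e-12)
        np.testing.assert_allclose(
            res["p"].to_numpy(), 2 * sps.norm.sf(np.abs(z)), rtol=1e-12
        )

    def test_q_never_below_p(self):
        rng = np.random.default_rng(13)
        res = moderated_t(self._data(rng), DESIGN, VariancePrior(d0=4.0, s0_sq=1.0))
        assert (res["q"] >= res["p"]).all()

    def test_incomplete_matrix_rejected(self):
        data = pd.DataFrame(
            [[1.0, np.nan, 3.0, 3.0, 2.0, 1.0]], index=["P1"], columns=list(DESIGN)
        )
        with pytest.raises(ValueError, match="complete"):
            moderated_t(data, DESIGN, VariancePrior(d0=4.0, s0_sq=1.0))

    def test_single_replicate_condition_rejected(self):
        design = {"a": "x", "b": "y", "c": "y"}
        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"], columns=list(design))
        with pytest.raises(ValueError, match="2 replicates"):
            moderated_t(data, design, VariancePrior(d0=4.0, s0_sq=1.0))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_against_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, bh_brute_force(p), rtol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.data(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_dominating(self, pvals, data):
        """q >= p elementwise; increasing one p never decreases any q."""
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        i = data.draw(st.integers(0, len(p) - 1))
        bumped = p.copy()
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 1.0)))
        q2 = bh_adjust(bumped)
        assert (q2 >= q - 1e-12).all()


class TestSignificanceCall:
    def test_strong_upregulation_called(self, config):
        # magnitude of the study's top respiratory-morphology protein
        assert significance_call(2.348, 0.01, config)

    def test_small_fold_change_never_called(self, config):
        assert not significance_call(0.5, 0.001, config)

    def test_curve_mode_threshold_shape(self):
        cfg = AnalysisConfig(sig_mode="curve", curve_steepness=1.0)
        # at |lfc| = lfc_min the effective threshold is 0
        assert not significance_call(1.0, 1e-12, cfg)
        # far out the threshold approaches q_max
        assert significance_call(60.0, 0.0499, cfg)
        assert not significance_call(60.0, 0.0501, cfg)


class TestAggregateCycles:
    def _cycle(self, lfc, p, q, index):
        return pd.DataFrame({"lfc": lfc, "t": lfc, "p": p, "q": q}, index=index)

    def test_single_cycle_is_identity(self, config):
        idx = ["P1", "P2"]
        cyc = self._cycle([2.0, 0.1], [0.001, 0.8], [0.002, 0.9], idx)
        out = aggregate_cycles([cyc], config)
        assert out.loc["P1", "significant"] and out.loc["P1", "direction"] == "up"
        assert not out.loc["P2", "significant"]
        np.testing.assert_allclose(out["lfc"], cyc["lfc"])

    def test_exact_half_fails_strict_majority(self, config):
        idx = ["P1"]
        sig = self._cycle([2.0], [0.001], [0.002], idx)
        ns = self._cycle([2.0], [0.5], [0.9], idx)
        out = aggregate_cycles([sig] * 10 + [ns] * 10, config)
        assert out.loc["P1", "n_cycles_significant"] == 10
        assert not out.loc["P1", "significant"]

    def test_lfc_is_hand_averaged_mean(self, config):
        idx = ["A", "B", "C"]
        cycles = [
            self._cycle([1.0, -2.0, 0.0], [0.5] * 3, [0.6] * 3, idx),
            self._cycle([2.0, -2.5, 0.3], [0.5] * 3, [0.6] * 3, idx),
            self._cycle([3.0, -1.5, -0.3], [0.5] * 3, [0.6] * 3, idx),
        ]
        out = aggregate_cycles(cycles, config)
        np.testing.assert_allclose(out["lfc"], [2.0, -2.0, 0.0])

    def test_inconsistent_protein_sets_rejected(self, config):
        a = self._cycle([1.0], [0.5], [0.5], ["P1"])
        b = self._cycle([1.0], [0.5], [0.5], ["P2"])
        with pytest.raises(ValueError, match="inconsistent"):
            aggregate_cycles([a, b], config)


class TestCountByThresholds:
    def test_empty_table(self, config):
        out = count_by_thresholds(pd.DataFrame(columns=["lfc", "p"]), config)
        assert all(v == 0 for v in out.values())

    def test_enumerated_example(self, config):
        table = pd.DataFrame(
            {"lfc": [0.6, -0.6, 0.4], "p": [0.01, 0.2, 0.001]},
            index=["A", "B", "C"],
        )
        out = count_by_thresholds(table, config)
        assert out == {
            "down": 1, "up": 1, "significant": 2,
            "nonsignificant": 1, "down_sig": 0, "up_sig": 1,
        }

    def test_strict_inequalities_at_boundaries(self, config):
        table = pd.DataFrame({"lfc": [0.5, -0.5], "p": [0.05, 0.04]}, index=["A", "B"])
        out = count_by_thresholds(table, config)
        assert out["up"] == 0 and out["down"] == 0 and out["significant"] == 1

    def test_row_order_invariance(self, config):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(
            {"lfc": rng.normal(0, 1, 50), "p": rng.random(50)},
            index=[f"P{i}" for i in range(50)],
        )
        shuffled = table.sample(frac=1, random_state=1)
        assert count_by_thresholds(table, config) == count_by_thresholds(shuffled, config)
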