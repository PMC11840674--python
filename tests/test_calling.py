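"""Differential-abundance DRTC calling: exact test, BH, gates, classes."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allotrace.calling import (
    bh_adjust,
    binomial_two_sided_p,
    call_drtc,
    classify_scatter,
)
from allotrace.io import RepertoireSample


def exact_minlike_p(k: int, n: int, p0: Fraction) -> Fraction:
    """Independent oracle: minimum-likelihood two-sided binomial p-value
    computed in exact rational arithmetic."""
    q0 = 1 - p0
    pmf = [comb(n, j) * p0**j * q0 ** (n - j) for j in range(n + 1)]
    return sum(pj for pj in pmf if pj <= pmf[k])


def bh_stepup_oracle(p, alpha):
    """Independent oracle: rejection set by exhaustive search over the
    step-up thresholds p_(k) <= k*alpha/m."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * alpha / m:
            k_star = rank
    if k_star == 0:
        return set()
    threshold = p[order[k_star - 1]]
    return {i for i in range(m) if p[i] <= threshold}


class TestBinomialTwoSided:
    @pytest.mark.parametrize(
        "ca,cb,ta,tb,expected",
        [
            (5, 0, 1000, 1000, 0.0625),  # symmetric null: both tails 1/32
            (3, 1, 1000, 3000, 0.05078125),  # P(3)+P(4) under p0=1/4
            (2, 2, 1000, 1000, 1.0),  # observed count is the mode
        ],
    )
    def test_worked_examples(self, ca, cb, ta, tb, expected):
        assert binomial_two_sided_p(ca, cb, ta, tb) == pytest.approx(expected, abs=1e-12)

    def test_matches_exact_enumeration_small_grid(self):
        for p0 in (Fraction(1, 4), Fraction(1, 10)):
            ta = int(p0 * 10_000)
            tb = 10_000 - ta
            for n in (1, 2, 5, 9, 17):
                for k in range(n + 1):
                    got = binomial_two_sided_p(k, n - k, ta, tb)
                    assert got == pytest.approx(
                        float(exact_minlike_p(k, n, p0)), abs=1e-12
                    )

    def test_doubling_option(self):
        # doubling the smaller tail: (5,0) at p0=1/2 gives 2*P(X>=5)=1/16
        assert binomial_two_sided_p(5, 0, 1000, 1000, method="doubling") == pytest.approx(
            0.0625
        )
        # at the mode the doubled tail exceeds 1 and is capped
        assert binomial_two_sided_p(2, 2, 1000, 1000, method="doubling") == 1.0

    def test_symmetry_under_sample_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ta, tb = rng.integers(100, 10_000, size=2)
            ca = int(rng.integers(0, 40))
            cb = int(rng.integers(0, 40))
            if ca + cb == 0:
                continue
            assert binomial_two_sided_p(ca, cb, ta, tb) == pytest.approx(
                binomial_two_sided_p(cb, ca, tb, ta), rel=1e-12
            )

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            binomial_two_sided_p(0, 0, 100, 100)

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            binomial_two_sided_p(11, 0, 10, 100)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01], [0.01]),
            ([0.005, 0.01, 0.03], [0.015, 0.015, 0.03]),
            ([0.5] * 10, [0.5] * 10),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_rejection_sets_match_stepup_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m = int(rng.integers(1, 21))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            q = bh_adjust(p)
            for alpha in (0.01, 0.05, 0.2):
                got = {i for i in range(m) if q[i] <= alpha}
                assert got == bh_stepup_oracle(list(p), alpha)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(q_sm)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_adjusted_never_below_raw_and_monotone(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


def pair(counts_mlr, counts_unstim):
    a = RepertoireSample.from_counts("mlr", counts_mlr, subset="cd4", subject_id="P")
    b = RepertoireSample.from_counts("unstim", counts_unstim, subject_id="P")
    return a, b


class TestCallDrtc:
    def test_newly_detected_expanded_clone_is_drtc(self):
        # one clone at 50/10,000 in the MLR, absent from 100,000 unstim
        # templates, over a balanced background
        background = {f"b{i}": 100 for i in range(99)}
        mlr = dict(background, spike=50, pad=50)
        unstim = {k: v * 10 for k, v in background.items()}
        unstim["pad"] = 1000 + 100 * 10  # absorb the spike's mass
        a, b = pair(mlr, unstim)
        drtc = call_drtc(a, b)
        assert "spike" in drtc.members
        assert drtc.results.loc["spike", "fold"] == np.inf

    def test_below_count_floor_regardless_of_totals(self):
        a, b = pair({"x": 4, "pad": 9996}, {"pad": 100_000})
        drtc = call_drtc(a, b)
        assert drtc.results.loc["x", "call"] == "below_count_floor"
        assert np.isnan(drtc.results.loc["x", "p_value"])

    def test_exactly_proportional_clone_not_significant(self):
        a, b = pair({"x": 10, "pad": 990}, {"x": 10, "pad": 990})
        drtc = call_drtc(a, b)
        assert drtc.results.loc["x", "call"] == "not_significant"
        assert drtc.results.loc["x", "fold"] == pytest.approx(1.0)

    def test_identical_samples_yield_no_calls(self):
        counts = {f"c{i}": 10 + i for i in range(50)}
        a, b = pair(counts, counts)
        drtc = call_drtc(a, b)
        assert len(drtc) == 0
        assert (drtc.results["call"] != "drtc").all()

    def test_alpha_out_of_range(self):
        a, b = pair({"x": 10}, {"x": 10})
        with pytest.raises(ValueError, match="alpha"):
            call_drtc(a, b, alpha=1.5)

    def test_swap_symmetry_maps_calls(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 200, size=80)
        mlr = {f"c{i}": int(v) for i, v in enumerate(base)}
        unstim = {f"c{i}": int(v) for i, v in enumerate(rng.permutation(base))}
        mlr["up"] = 500
        unstim["down"] = 500
        a, b = pair(mlr, unstim)
        fwd = call_drtc(a, b).results
        rev = call_drtc(b, a).results
        common = fwd.index.intersection(rev.index)
        assert fwd.loc[common, "p_value"].fillna(-1).tolist() == pytest.approx(
            rev.loc[common, "p_value"].fillna(-1).tolist()
        )
        swap = {"drtc": "enriched_unstim", "enriched_unstim": "drtc"}
        for clone in common:
            f_call = fwd.loc[clone, "call"]
            assert rev.loc[clone, "call"] == swap.get(f_call, f_call)

    def test_multiplicity_counts_only_tested_clones(self):
        # clones below the floor never receive a p-value and never enter BH
        a, b = pair({"x": 2, "big": 1000}, {"x": 1, "big": 1000})
        drtc = call_drtc(a, b)
        tested = drtc.results["p_value"].notna()
        assert tested.sum() == 1  # only "big"
        assert not tested.loc["x"]

    def test_qvalue_at_least_pvalue(self):
        rng = np.random.default_rng(11)
        mlr = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1, 100, 200))}
        unstim = {f"c{i}": int(v) for i, v in enumerate(rng.integers(1, 100, 200))}
        res = call_drtc(*pair(mlr, unstim)).results
        tested = res.dropna(subset=["p_value"])
        assert (tested["q_value"] >= tested["p_value"] - 1e-15).all()

    def test_parameters_recorded(self):
        a, b = pair({"x": 10}, {"x": 10})
        drtc = call_drtc(a, b, alpha=0.05, fold_min=3.0, count_floor=7)
        assert drtc.parameters["alpha"] == 0.05
        assert drtc.parameters["fold_min"] == 3.0
        assert drtc.parameters["count_floor"] == 7


class TestClassifyScatter:
    def test_partition_sums_to_universe(self):
        rng = np.random.default_rng(9)
        mlr = {f"c{i}": int(v) for i, v in enumerate(rng.integers(0, 60, 100)) if v}
        unstim = {f"c{i}": int(v) for i, v in enumerate(rng.integers(0, 60, 100)) if v}
        res = call_drtc(*pair(mlr, unstim)).results
        counts = classify_scatter(res)
        assert sum(counts.values()) == len(res)

    def test_empty_table(self):
        import pandas as pd

        counts = classify_scatter(pd.DataFrame(columns=["call"]))
        assert all(v == 0 for v in counts.values())
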