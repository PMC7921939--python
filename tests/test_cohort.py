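"""Cohort statistics: frequencies, log2 ratio, cumulative curves, tests."""

import math

import numpy as np
import pandas as pd
import pytest

from synquant import (
    PATTERNS,
    central_invagination_ratio,
    compare_conditions,
    cumulative_off_interface,
    pattern_frequencies,
)
from synquant.config import StatsParams


def _timelines(labels_by_time: dict[float, list[str]]):
    """Build per-couple timelines from per-time label lists."""
    n = max(len(v) for v in labels_by_time.values())
    return [
        {t: labs[i] for t, labs in labels_by_time.items() if i < len(labs)}
        for i in range(n)
    ]


class TestPatternFrequencies:
    def test_all_central_is_hundred_percent(self):
        tls = _timelines({0.0: ["central"] * 10})
        table = pattern_frequencies(tls, "c")
        row = table[(table.pattern == "central")].iloc[0]
        assert row.percent == 100.0 and row.n == 10
        others = table[~table.pattern.isin(["central", "any"])]
        assert (others.percent == 0).all()

    def test_percents_partition_to_hundred(self):
        rng = np.random.default_rng(0)
        labs = [PATTERNS[i] for i in rng.integers(0, 7, size=37)]
        table = pattern_frequencies(_timelines({20.0: labs}), "c")
        total = table[table.pattern.isin(PATTERNS)].percent.sum()
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_any_pattern_row(self):
        labs = ["none"] * 6 + ["central"] * 3 + ["diffuse"]
        table = pattern_frequencies(_timelines({0.0: labs}), "c")
        assert table[table.pattern == "any"].percent.iloc[0] == 40.0

    def test_binomial_standard_error(self):
        labs = ["central"] * 42 + ["none"] * 58
        table = pattern_frequencies(_timelines({0.0: labs}), "c")
        se = table[table.pattern == "central"].se.iloc[0]
        assert se == pytest.approx(100 * math.sqrt(0.42 * 0.58 / 100))

    def test_missing_timepoints_drop_from_denominator(self):
        tls = [{0.0: "central", 20.0: "central"}, {0.0: "none"}]
        table = pattern_frequencies(tls, "c")
        assert table[table.time_rel_s == 20.0].n.iloc[0] == 1


class TestRatioSeries:
    def _table(self, central, invagination, n=100, t=20.0):
        labs = (
            ["central"] * central
            + ["invagination"] * invagination
            + ["none"] * (n - central - invagination)
        )
        return pattern_frequencies(_timelines({t: labs}), "c")

    def test_equal_counts_give_zero(self):
        table = self._table(10, 10)
        r = central_invagination_ratio(table)
        assert r.log2_central_over_invagination.iloc[0] == 0.0

    def test_forty_over_ten(self):
        # log2((40 + 0.5) / (10 + 0.5)) = 1.9475
        table = self._table(40, 10)
        r = central_invagination_ratio(table)
        assert r.log2_central_over_invagination.iloc[0] == pytest.approx(
            math.log2(40.5 / 10.5), abs=1e-12
        )
        assert abs(r.log2_central_over_invagination.iloc[0] - 2.0) < 0.1

    def test_effector_scenario_is_central_preferring(self):
        # 42 central vs 13 invagination per 100: log2(42.5/13.5) = 1.654 > 0
        table = self._table(42, 13)
        val = central_invagination_ratio(
            table
        ).log2_central_over_invagination.iloc[0]
        assert val == pytest.approx(math.log2(42.5 / 13.5), abs=1e-12)
        assert val > 0

    def test_zero_count_stays_finite(self):
        table = self._table(12, 0)
        val = central_invagination_ratio(
            table
        ).log2_central_over_invagination.iloc[0]
        assert np.isfinite(val) and val == pytest.approx(
            math.log2(12.5 / 0.5)
        )

    def test_sign_tracks_count_ordering(self):
        for c, i in ((30, 5), (5, 30), (17, 17)):
            val = central_invagination_ratio(
                self._table(c, i)
            ).log2_central_over_invagination.iloc[0]
            assert np.sign(val) == np.sign(c - i)


class TestCumulativeOffInterface:
    def _morph(self, flag_times: dict[int, float], n_couples: int):
        rows = []
        grid = StatsParams().grid()
        for cid in range(n_couples):
            for t in grid:
                rows.append(
                    {
                        "couple_id": cid,
                        "time_rel_s": float(t),
                        "has_off_interface_lamella": (
                            cid in flag_times and t == flag_times[cid]
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def test_no_flags_is_zero_everywhere(self):
        curve = cumulative_off_interface(self._morph({}, 8))
        assert (curve.cumulative_percent == 0).all()

    def test_curve_equals_empirical_cdf(self):
        flag_times = {0: 20.0, 1: 20.0, 2: 60.0, 3: 120.0}
        curve = cumulative_off_interface(self._morph(flag_times, 10))
        times = np.array(sorted(flag_times.values()))
        for _, row in curve.iterrows():
            expected = 100 * (times <= row.time_rel_s).mean() * len(times) / 10
            assert row.cumulative_percent == pytest.approx(expected)

    def test_monotone_non_decreasing(self):
        flag_times = {i: 20.0 * (i + 1) for i in range(6)}
        curve = cumulative_off_interface(self._morph(flag_times, 12))
        assert (np.diff(curve.cumulative_percent) >= 0).all()

    def test_pre_coupling_flags_ignored(self):
        curve = cumulative_off_interface(self._morph({0: -20.0}, 5))
        assert (curve.cumulative_percent == 0).all()


def _hypergeom_two_sided(ka, na, kb, nb):
    """Brute-force two-sided Fisher p: sum of table probabilities no more
    likely than the observed one, enumerating the hypergeometric support."""
    total, k = na + nb, ka + kb
    lo, hi = max(0, k - nb), min(k, na)
    logp = {}
    for x in range(lo, hi + 1):
        logp[x] = (
            math.lgamma(na + 1) - math.lgamma(x + 1)
            - math.lgamma(na - x + 1)
            + math.lgamma(nb + 1) - math.lgamma(k - x + 1)
            - math.lgamma(nb - (k - x) + 1)
            - (math.lgamma(total + 1) - math.lgamma(k + 1)
               - math.lgamma(total - k + 1))
        )
    p_obs = logp[ka]
    return sum(math.exp(v) for v in logp.values() if v <= p_obs + 1e-12)


class TestCompareConditions:
    def _table(self, central, n, cond):
        labs = ["central"] * central + ["none"] * (n - central)
        return pattern_frequencies(_timelines({20.0: labs}), cond)

    def test_identical_tables_give_p_one(self):
        a = self._table(12, 40, "a")
        comp = compare_conditions(a, a, patterns=["central"])
        assert (comp.p_raw == 1.0).all()

    def test_exact_test_matches_hypergeometric_enumeration(self):
        a = self._table(42, 100, "a")
        b = self._table(5, 100, "b")
        comp = compare_conditions(a, b, patterns=["central"])
        p = comp.p_raw.iloc[0]
        assert p < 0.001
        assert p == pytest.approx(_hypergeom_two_sided(42, 100, 5, 100),
                                  rel=1e-6)

    def test_holm_never_below_raw(self):
        rng = np.random.default_rng(3)
        tls_a, tls_b = [], []
        for cid in range(30):
            tls_a.append(
                {t: ("central" if rng.random() < 0.4 else "none")
                 for t in (0.0, 20.0, 40.0, 60.0)}
            )
            tls_b.append(
                {t: ("central" if rng.random() < 0.15 else "none")
                 for t in (0.0, 20.0, 40.0, 60.0)}
            )
        a = pattern_frequencies(tls_a, "a")
        b = pattern_frequencies(tls_b, "b")
        comp = compare_conditions(a, b, patterns=["central"])
        assert (comp.p_holm >= comp.p_raw - 1e-12).all()
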