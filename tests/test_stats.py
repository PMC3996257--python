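"""Exact Wilcoxon signed-rank and Spearman against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from ermetrics.cohort_stats import (
    CorrelationResult,
    PairedSample,
    build_report,
    correlate_deltas,
    spearman,
    summarize_area,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def wilcoxon_p_enumeration(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev_obs = abs(w_obs - total / 2.0)
    signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
    w_all = signs @ ranks
    return float(np.mean(np.abs(w_all - total / 2.0) >= dev_obs - 1e-12))


def spearman_perm_p_enumeration(x, y):
    """Two-sided exact permutation p, recomputing rho for every permutation."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        rho = np.corrcoef(rx, perm)[0, 1]
        if abs(rho) >= rho_obs - 1e-9:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_all_positive_n16_is_two_over_2_pow_16(self):
        pre = tuple(float(i + 10) for i in range(16))
        post = tuple(float(i) for i in range(16))
        res = wilcoxon_signed_rank(PairedSample(pre, post))
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(2.0 / 2.0**16, abs=0.0)

    def test_symmetric_pair_gives_p_one(self):
        res = wilcoxon_signed_rank(PairedSample((1.0, 0.0), (0.0, 1.0)))
        assert res.p_two_sided == pytest.approx(1.0)

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank(PairedSample((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)))
        assert res.p_two_sided == 1.0 and res.n_effective == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_equals_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        # mix of continuous and tie-prone integer differences, some zeros
        if seed % 2:
            d = rng.integers(-4, 5, n).astype(float)
        else:
            d = rng.normal(0.4, 1.0, n)
        if not np.any(d != 0):
            d[0] = 1.0
        pre = np.zeros(n) + d
        res = wilcoxon_signed_rank(PairedSample(tuple(pre), tuple(np.zeros(n))))
        want = wilcoxon_p_enumeration(d)
        assert res.p_two_sided == pytest.approx(want, abs=1e-12)

    def test_missing_pairs_dropped(self):
        res = wilcoxon_signed_rank(
            PairedSample((1.0, None, 3.0, 4.0), (0.0, 5.0, 1.0, None))
        )
        assert res.n_effective == 2

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 1.0, 40)
        res = wilcoxon_signed_rank(PairedSample(tuple(d), tuple(np.zeros(40))))
        assert res.method == "normal-approx"
        ref = sps.wilcoxon(d, mode="approx", correction=True)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=0.01)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_monotone_series_give_plus_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0, 15.0, 20.0, 21.0, 22.0, 23.0]
        y = [v**3 for v in x]
        assert spearman(x, y).rho == pytest.approx(1.0)
        assert spearman(x, y[::-1]).rho == pytest.approx(-1.0)

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 20).astype(float)
        y = rng.integers(0, 5, 20).astype(float) + 0.3 * x
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=0.02)

    def test_exact_permutation_p_matches_enumeration_n8_with_tie(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0]
        res = spearman(x, y)
        assert res.method == "exact-permutation"
        want = spearman_perm_p_enumeration(x, y)
        assert res.p_two_sided == pytest.approx(want, abs=1e-12)

    def test_zero_rank_variance_flagged(self):
        with pytest.warns(UserWarning):
            res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.rho) and res.method == "undefined"

    @given(
        st.lists(
            st.integers(-100, 100), min_size=10, max_size=16, unique=True
        ).map(sorted)
    )
    def test_invariant_under_strictly_monotone_transform(self, x):
        rng = np.random.default_rng(42)
        y = rng.normal(size=len(x))
        base = spearman(x, y)
        transformed = spearman([math.atan(v / 50.0) for v in x], y)
        assert transformed.rho == pytest.approx(base.rho, abs=1e-12)


# ---------------------------------------------------------------------------
# cohort rows and report
# ---------------------------------------------------------------------------


def _hand_cohort():
    from ermetrics.grid_metrics import (
        FBLResult,
        QUADRANTS,
        QuadrantVLA,
        SubfieldMetrics,
        pair_metrics,
    )

    cohort = []
    pre_vla = [1000.0, 1200.0, 1400.0]
    post_vla = [900.0, 1050.0, 1200.0]
    for i, (a, b) in enumerate(zip(pre_vla, post_vla)):
        pre = SubfieldMetrics(
            "pre",
            vla={q: QuadrantVLA(a, 3, (a,) * 3) for q in QUADRANTS},
            fbl={"superior": FBLResult(9000.0 + 50 * i, (1800.0,) * 5, ("x",) * 5),
                 "inferior": FBLResult(9100.0, (1820.0,) * 5, ("y",) * 5)},
            mt={"central": 360.0 - i, "superior": 340.0, "inferior": 335.0,
                "nasal": 370.0, "temporal": 372.0},
        )
        post = SubfieldMetrics(
            "post",
            vla={q: QuadrantVLA(b, 3, (b,) * 3) for q in QUADRANTS},
            fbl={"superior": FBLResult(9400.0 + 60 * i, (1880.0,) * 5, ("x",) * 5),
                 "inferior": FBLResult(9500.0, (1900.0,) * 5, ("y",) * 5)},
            mt={"central": 300.0 - 2 * i, "superior": 300.0, "inferior": 290.0,
                "nasal": 330.0, "temporal": 310.0},
        )
        cohort.append(pair_metrics(pre, post, 0.3 + 0.01 * i, 0.1, eye_id=f"e{i}"))
    return cohort


class TestCohortRows:
    def test_summarize_area_hand_values(self):
        cohort = _hand_cohort()
        row = summarize_area(cohort, "vla", "superior")
        assert row.pre_mean == pytest.approx(1200.0)
        assert row.post_mean == pytest.approx(1050.0)
        assert row.pre_median == pytest.approx(1200.0)
        assert row.post_median == pytest.approx(1050.0)
        # two-pass oracle for the SD
        vals = np.array([1000.0, 1200.0, 1400.0])
        sd = math.sqrt(((vals - vals.mean()) ** 2).sum() / (len(vals) - 1))
        assert row.pre_sd == pytest.approx(sd)
        # quartiles by linear interpolation between order statistics
        assert row.pre_q25 == pytest.approx(1100.0)
        assert row.pre_q75 == pytest.approx(1300.0)

    def test_identical_visits_give_p_one(self):
        cohort = _hand_cohort()
        for p in cohort:
            p.post = p.pre.__class__(
                visit="post", vla=p.pre.vla, fbl=p.pre.fbl, mt=p.pre.mt
            )
        with pytest.warns(UserWarning):
            row = summarize_area(cohort, "vla", "superior")
        assert row.p_value == 1.0

    def test_correlate_self_is_one(self):
        res = correlate_deltas(_hand_cohort(), "vla", "vla", x_area="superior", y_area="superior")
        assert res.rho == pytest.approx(1.0)

    def test_report_complete_and_recomputable(self):
        cohort = _hand_cohort()
        report = build_report(cohort)
        assert len(report.comparison) == 4 + 2 + 5 + 1
        row = next(r for r in report.comparison if r.label == "vla:superior")
        direct = summarize_area(cohort, "vla", "superior")
        assert row == direct
        frames = report.to_frames()
        assert set(frames) == {"comparison", "correlations", "bcva"}
        assert len(frames["comparison"]) == len(report.comparison)

    def test_report_deterministic_via_saved_csv(self, tmp_path):
        from ermetrics import io as _io

        cohort = _hand_cohort()
        _io.save_cohort_csv(cohort, tmp_path / "cohort.csv")
        loaded = _io.load_cohort_csv(tmp_path / "cohort.csv")
        r1 = build_report(loaded)
        r2 = build_report(_io.load_cohort_csv(tmp_path / "cohort.csv"))
        r1.save(tmp_path / "a")
        r2.save(tmp_path / "b")
        assert (tmp_path / "a" / "report.json").read_text() == (
            tmp_path / "b" / "report.json"
        ).read_text()
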