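"""Paired nonparametric statistics over a cohort of pre/post eye visits.

Reproduces the clinical analysis plan: exact Wilcoxon signed-rank tests
comparing pre- and post-operative BCVA, VLA, FBL and macular thickness,
and Spearman correlations between the Δ series (Δ sign conventions:
ΔVLA/ΔMT/ΔCMT/ΔBCVA = pre − post, ΔFBL = post − pre).  At the study's
n = 16 the Wilcoxon p-value is exact — computed from the full null
distribution of the positive-rank sum over all 2^n sign assignments —
and the Spearman p is exact by permutation for very small n.
No multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .grid_metrics import EyeVisitPair, FBL_QUADRANTS, QUADRANTS, SUBFIELDS

__all__ = [
    "PairedSample",
    "TestResult",
    "CorrelationResult",
    "AreaSummary",
    "CorrRow",
    "CohortReport",
    "wilcoxon_signed_rank",
    "spearman",
    "collect_series",
    "summarize_area",
    "correlate_deltas",
    "build_report",
]

EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class PairedSample:
    """Equal-length pre/post value lists (μm or logMAR); missing entries
    (NaN/None) are removed pairwise before testing."""

    values_pre: tuple[float, ...]
    values_post: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.values_pre) != len(self.values_post):
            raise ValueError("values_pre and values_post must have equal length")
        if len(self.values_pre) < 2:
            raise ValueError("need at least 2 pairs")

    def differences(self) -> np.ndarray:
        pre = np.array([np.nan if v is None else v for v in self.values_pre], dtype=float)
        post = np.array([np.nan if v is None else v for v in self.values_post], dtype=float)
        d = pre - post
        return d[~np.isnan(d)]


@dataclass(frozen=True)
class TestResult:
    statistic_w: float  # positive-rank sum W+
    p_two_sided: float
    n_effective: int
    method: str  # exact | normal-approx


def _signed_rank_parts(diffs: np.ndarray, zero_method: str) -> tuple[np.ndarray, float]:
    """Ranks entering the statistic and the observed W+ (positive-rank sum)."""
    diffs = np.asarray(diffs, dtype=float)
    if zero_method == "wilcox":
        diffs = diffs[diffs != 0]
        ranks = sps.rankdata(np.abs(diffs))
        w_pos = float(ranks[diffs > 0].sum())
        return ranks, w_pos
    if zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(diffs))
        nz = diffs != 0
        w_pos = float(ranks_all[diffs > 0].sum())
        return ranks_all[nz], w_pos
    raise ValueError(f"unknown zero_method {zero_method!r}")


def _exact_two_sided_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p from the full sign-assignment null distribution.

    The null distribution of W+ (sum of the ranks carrying a positive
    sign, over all 2^n equiprobable sign vectors) is symmetric about T/2
    with T = Σ ranks; the two-sided p is the null probability of a
    deviation |W+ − T/2| at least as large as observed.  Average ranks are
    half-integers, so everything is done in doubled-integer arithmetic and
    the result is exact.
    """
    r2 = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(np.int64)
    t2 = int(r2.sum())
    counts = np.zeros(t2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: t2 + 1 - r]
        counts = counts + shifted
    w2 = int(round(2.0 * w_pos))
    dev = abs(2 * w2 - t2)
    sums2 = 2 * np.arange(t2 + 1) - t2
    p = counts[np.abs(sums2) >= dev].sum() / 2.0 ** len(r2)
    return float(min(p, 1.0))


def wilcoxon_signed_rank(
    sample: PairedSample, zero_method: str = "wilcox"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on pre − post differences.

    Zero differences are dropped before ranking (classic Wilcoxon rule;
    ``zero_method="pratt"`` ranks them and drops them from the statistic).
    The p-value is exact — equal to full 2^n sign enumeration — when the
    effective n ≤ 25, otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    diffs = sample.differences()
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, 0, "degenerate")
    if len(nonzero) < 2:
        warnings.warn("fewer than 2 nonzero differences", stacklevel=2)
    ranks, w_pos = _signed_rank_parts(diffs, zero_method)
    n_eff = len(ranks)
    if n_eff <= EXACT_WILCOXON_MAX_N:
        return TestResult(w_pos, _exact_two_sided_p(ranks, w_pos), n_eff, "exact")
    t = float(ranks.sum())
    mean = t / 2.0
    sd = math.sqrt(float((ranks**2).sum()) / 4.0)
    z = (w_pos - mean - 0.5 * math.copysign(1.0, w_pos - mean)) / sd if sd > 0 else 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(w_pos, float(min(p, 1.0)), n_eff, "normal-approx")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    method: str = "t-approx"  # exact-permutation | t-approx | undefined


def _pairwise_complete(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.array([np.nan if v is None else v for v in x], dtype=float)
    ya = np.array([np.nan if v is None else v for v in y], dtype=float)
    ok = ~np.isnan(xa) & ~np.isnan(ya)
    return xa[ok], ya[ok]


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p by exact permutation of the rank vector when n ≤ 9 (all
    n! permutations, conditioning on the observed tie pattern), else by
    the t approximation ``t = rho·sqrt((n−2)/(1−rho²))``.
    """
    xa, ya = _pairwise_complete(x, y)
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    if np.std(rx) == 0 or np.std(ry) == 0:
        warnings.warn("zero variance in ranks; Spearman rho undefined", stacklevel=2)
        return CorrelationResult(float("nan"), float("nan"), n, "undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        # rho is monotone in S = Σ rx·ry(perm) for fixed marginals
        s_obs = float(rx @ ry)
        centre = n * rx.mean() * ry.mean()
        dev = abs(s_obs - centre) - 1e-9
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            s = float(rx @ np.asarray(perm))
            if abs(s - centre) >= dev:
                count += 1
            total += 1
        return CorrelationResult(rho, count / total, n, "exact-permutation")
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, "t-approx")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(rho, float(min(p, 1.0)), n, "t-approx")


# ---------------------------------------------------------------------------
# Cohort series access
# ---------------------------------------------------------------------------


def _metric_value(pair: EyeVisitPair, metric: str, area: str | None, kind: str) -> float | None:
    """One cell of the cohort table.

    metric ∈ {vla, fbl, mt, cmt, bcva}; area a quadrant/subfield or "sum";
    kind ∈ {pre, post, delta}.
    """
    if metric == "bcva":
        return {"pre": pair.bcva_pre, "post": pair.bcva_post, "delta": pair.d_bcva}[kind]
    if metric == "cmt":
        metric, area = "mt", "central"
    if metric == "vla":
        if area == "sum":
            if kind == "delta":
                return pair.d_vla_sum
            vis = pair.pre if kind == "pre" else pair.post
            vals = [vis.vla_value(q) for q in QUADRANTS]
            return None if any(v is None for v in vals) else float(sum(vals))
        if kind == "delta":
            return pair.d_vla(area)
        return (pair.pre if kind == "pre" else pair.post).vla_value(area)
    if metric == "fbl":
        if area == "sum":
            if kind == "delta":
                return pair.d_fbl_sum
            vis = pair.pre if kind == "pre" else pair.post
            vals = [vis.fbl_value(q) for q in FBL_QUADRANTS]
            return None if any(v is None for v in vals) else float(sum(vals))
        if kind == "delta":
            return pair.d_fbl(area)
        return (pair.pre if kind == "pre" else pair.post).fbl_value(area)
    if metric == "mt":
        if kind == "delta":
            return pair.d_mt(area)
        return (pair.pre if kind == "pre" else pair.post).mt_value(area)
    raise ValueError(f"unknown metric {metric!r}")


def collect_series(
    cohort: Sequence[EyeVisitPair], metric: str, area: str | None = None, kind: str = "delta"
) -> np.ndarray:
    """Cohort-aligned series of one metric (NaN where missing)."""
    return np.array(
        [np.nan if (v := _metric_value(p, metric, area, kind)) is None else v for p in cohort],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# Report rows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AreaSummary:
    """One comparison-table row: descriptive statistics of the pre and post
    values plus the paired Wilcoxon p.  Quartiles use linear interpolation
    between order statistics (pinned; statistical packages differ)."""

    label: str
    n: int
    pre_mean: float | None = None
    pre_sd: float | None = None
    pre_median: float | None = None
    pre_q25: float | None = None
    pre_q75: float | None = None
    post_mean: float | None = None
    post_sd: float | None = None
    post_median: float | None = None
    post_q25: float | None = None
    post_q75: float | None = None
    p_value: float | None = None
    missing: bool = False


def _describe(v: np.ndarray) -> tuple[float, float, float, float, float]:
    return (
        float(np.mean(v)),
        float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        float(np.quantile(v, 0.5, method="linear")),
        float(np.quantile(v, 0.25, method="linear")),
        float(np.quantile(v, 0.75, method="linear")),
    )


def summarize_area(
    cohort: Sequence[EyeVisitPair], metric: str, area: str | None = None
) -> AreaSummary:
    """Pre/post descriptive statistics and paired Wilcoxon test for one
    metric/area over the cohort (pairwise-complete eyes only)."""
    pre = collect_series(cohort, metric, area, "pre")
    post = collect_series(cohort, metric, area, "post")
    ok = ~np.isnan(pre) & ~np.isnan(post)
    label = f"{metric}:{area}" if area else metric
    if ok.sum() < 2:
        return AreaSummary(label=label, n=int(ok.sum()), missing=True)
    pre, post = pre[ok], post[ok]
    test = wilcoxon_signed_rank(PairedSample(tuple(pre), tuple(post), label))
    pm, psd, pmed, p25, p75 = _describe(pre)
    qm, qsd, qmed, q25, q75 = _describe(post)
    return AreaSummary(
        label=label, n=len(pre),
        pre_mean=pm, pre_sd=psd, pre_median=pmed, pre_q25=p25, pre_q75=p75,
        post_mean=qm, post_sd=qsd, post_median=qmed, post_q25=q25, post_q75=q75,
        p_value=test.p_two_sided,
    )


def correlate_deltas(
    cohort: Sequence[EyeVisitPair],
    x_metric: str,
    y_metric: str,
    x_area: str | None = None,
    y_area: str | None = None,
    x_kind: str = "delta",
    y_kind: str = "delta",
) -> CorrelationResult:
    """Spearman correlation between two cohort series (Δ by default; BCVA
    variants use ``kind`` = "pre"/"post")."""
    x = collect_series(cohort, x_metric, x_area, x_kind)
    y = collect_series(cohort, y_metric, y_area, y_kind)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    return spearman(x[ok], y[ok])


@dataclass(frozen=True)
class CorrRow:
    """One correlation-table row: Δ descriptives and Spearman r/p vs the
    thickness delta of the same area (sums vs ΔCMT)."""

    label: str
    n: int
    delta_mean: float | None = None
    delta_sd: float | None = None
    rho: float | None = None
    p_value: float | None = None
    missing: bool = False


def _corr_row(
    cohort: Sequence[EyeVisitPair], metric: str, area: str, against_area: str
) -> CorrRow:
    d = collect_series(cohort, metric, area, "delta")
    mt = collect_series(cohort, "mt", against_area, "delta")
    ok = ~np.isnan(d) & ~np.isnan(mt)
    label = f"d_{metric}:{area}"
    if ok.sum() < 3:
        return CorrRow(label=label, n=int(ok.sum()), missing=True)
    res = spearman(d[ok], mt[ok])
    return CorrRow(
        label=label, n=int(ok.sum()),
        delta_mean=float(np.mean(d[ok])),
        delta_sd=float(np.std(d[ok], ddof=1)) if ok.sum() > 1 else 0.0,
        rho=res.rho, p_value=res.p_two_sided,
    )


@dataclass
class CohortReport:
    """Structured cohort analysis: a pre-vs-post comparison block, a
    Δ-vs-ΔMT correlation block, and a BCVA block.  Every number is
    recomputable from the cohort."""

    comparison: list[AreaSummary] = field(default_factory=list)
    correlations: list[CorrRow] = field(default_factory=list)
    bcva: dict[str, float | None] = field(default_factory=dict)

    def to_frames(self):
        import pandas as pd
        from dataclasses import asdict

        return {
            "comparison": pd.DataFrame([asdict(r) for r in self.comparison]),
            "correlations": pd.DataFrame([asdict(r) for r in self.correlations]),
            "bcva": pd.DataFrame([self.bcva]),
        }

    def save(self, outdir) -> None:
        import json
        from pathlib import Path
        from dataclasses import asdict

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frames = self.to_frames()
        for name, df in frames.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        payload = {
            "schema_version": 1,
            "comparison": [asdict(r) for r in self.comparison],
            "correlations": [asdict(r) for r in self.correlations],
            "bcva": self.bcva,
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=2, allow_nan=True))


def build_report(cohort: Sequence[EyeVisitPair]) -> CohortReport:
    """Full cohort report: VLA/FBL/MT comparison rows, Δ correlation rows
    (per area and sums vs ΔCMT), and the BCVA block with the
    ΔVLA/ΔFBL-vs-acuity correlations."""
    if not cohort:
        raise ValueError("cohort is empty")
    report = CohortReport()
    for q in QUADRANTS:
        report.comparison.append(summarize_area(cohort, "vla", q))
    for q in FBL_QUADRANTS:
        report.comparison.append(summarize_area(cohort, "fbl", q))
    for s in SUBFIELDS:
        report.comparison.append(summarize_area(cohort, "mt", s))
    report.comparison.append(summarize_area(cohort, "bcva"))

    for q in QUADRANTS:
        report.correlations.append(_corr_row(cohort, "vla", q, q))
    report.correlations.append(_corr_row(cohort, "vla", "sum", "central"))
    for q in FBL_QUADRANTS:
        report.correlations.append(_corr_row(cohort, "fbl", q, q))
    report.correlations.append(_corr_row(cohort, "fbl", "sum", "central"))

    bcva: dict[str, float | None] = {}
    for metric in ("vla", "fbl"):
        for kind, name in (("pre", "bcva_pre"), ("post", "bcva_post"), ("delta", "d_bcva")):
            try:
                res = correlate_deltas(cohort, metric, "bcva", x_area="sum", y_kind=kind)
                bcva[f"rho_d{metric}_sum_vs_{name}"] = res.rho
                bcva[f"p_d{metric}_sum_vs_{name}"] = res.p_two_sided
            except ValueError:
                bcva[f"rho_d{metric}_sum_vs_{name}"] = None
                bcva[f"p_d{metric}_sum_vs_{name}"] = None
    report.bcva = bcva
    return report
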