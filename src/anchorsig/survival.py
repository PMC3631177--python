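"""Kaplan-Meier estimation, log-rank testing, and marker-based prognosis.

The product-limit estimator and the k-group log-rank chi-square are
implemented directly on the risk-set tabulation so that per-time at-risk and
event counts, and per-group observed/expected totals, are first-class outputs
(they are the quantities a prognosis report prints).  Ties follow the
standard convention: at a tied instant, events are processed before
censorings.

Marker stratification dichotomizes expression at the median computed over the
samples *with survival data*, then compares high vs low (single scheme) or
the four high/low combinations of two markers (combined scheme), including
the A-high&B-high vs A-high&B-low contrast that asks whether the second
marker adds prognostic value among samples already high for the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ExpressionCohort, SampleMetadata
from .stratify import AT_CUTPOINT, HIT, CutpointConfig, dichotomize

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray  # ascending distinct times with >= 1 event
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # estimate just after each event time
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event time."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


@dataclass
class LogRankResult:
    """k-group log-rank test summary."""

    chi_square: float
    df: int
    p_value: float
    group_sizes: list[int]
    observed: list[float]
    expected: list[float]


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` flags 1 = event, 0 = censored.  Censored times reduce the risk
    set without a step; all events at a tied time are processed together.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one observation")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")

    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uts = np.unique(ts)
    # risk set at u: everyone with time >= u (events at u counted before censorings at u)
    n_at = ts.size - np.searchsorted(ts, uts, side="left")
    d = np.array([es[ts == u].sum() for u in uts])

    keep = d > 0
    ev_times, n_ev, d_ev = uts[keep], n_at[keep], d[keep]
    surv = np.cumprod(1.0 - d_ev / n_ev) if d_ev.size else np.array([])
    return SurvivalCurve(
        event_times=ev_times,
        at_risk=n_ev.astype(int),
        events=d_ev.astype(int),
        survival=surv,
        n=int(t.size),
    )


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> LogRankResult:
    """Standard k-group log-rank chi-square with k-1 degrees of freedom.

    At every distinct event time the observed events per group are compared
    with expectation proportional to the group's share of the risk set; the
    covariance uses the hypergeometric variance.  Zero events overall is a
    hard error (the statistic is undefined).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    sizes = []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        if (t < 0).any():
            raise ValueError("negative survival time")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
        sizes.append(int(t.size))
    t_all = np.concatenate(times)
    e_all = np.concatenate(events)
    g_all = np.concatenate(labels)
    if e_all.sum() == 0:
        raise ValueError("no events in any group: log-rank statistic undefined")

    ev_times = np.unique(t_all[e_all == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for u in ev_times:
        at_risk = t_all >= u
        n_t = at_risk.sum()
        d_t = int(e_all[(t_all == u)].sum())
        n_g = np.array([(at_risk & (g_all == g)).sum() for g in range(k)], dtype=float)
        d_g = np.array(
            [int(e_all[(t_all == u) & (g_all == g)].sum()) for g in range(k)], dtype=float
        )
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            hyper = d_t * (n_t - d_t) / (n_t - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))

    x = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(x @ np.linalg.solve(Vsub, x))
    except np.linalg.LinAlgError:
        chi2 = float(x @ np.linalg.pinv(Vsub) @ x)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1))
    return LogRankResult(
        chi_square=chi2,
        df=k - 1,
        p_value=p,
        group_sizes=sizes,
        observed=list(O),
        expected=list(E),
    )


def survival_past_time_chisq(
    groups: Sequence[tuple[Sequence[float], Sequence[int]]], horizon: float
) -> tuple[float, float]:
    """Contingency chi-square on surviving past a fixed time (audit variant).

    Counts, per group, subjects known to survive past ``horizon`` vs subjects
    with an event at or before it (censored-before-horizon subjects are
    dropped).  Provided for fidelity auditing of reports that call a
    chi-square on survival tables; the log-rank test is the primary analysis.
    """
    table = []
    for t, e in groups:
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        alive = int((t > horizon).sum())
        dead = int(((t <= horizon) & (e == 1)).sum())
        table.append([alive, dead])
    chi2, p, _, _ = stats.chi2_contingency(np.array(table))
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Marker stratification
# ---------------------------------------------------------------------------


@dataclass
class StratifiedSurvival:
    """Curves and tests for one marker-stratified prognosis analysis."""

    scheme: str
    strata: dict[str, str]  # sample_id -> stratum label
    curves: dict[str, SurvivalCurve]
    tests: dict[str, LogRankResult]
    skipped: dict[str, str] = field(default_factory=dict)
    cutpoints: dict[str, float] = field(default_factory=dict)


def _apply_horizon(months: np.ndarray, event: np.ndarray, horizon: float | None):
    if horizon is None:
        return months, event
    capped = np.minimum(months, horizon)
    ev = np.where(months > horizon, 0, event)
    return capped, ev


def stratify_and_test(
    cohort: ExpressionCohort,
    metadata: Iterable[SampleMetadata],
    marker_a: str,
    marker_b: str | None = None,
    scheme: str = "single",
    min_samples: int = 10,
    horizon: float | None = None,
) -> StratifiedSurvival:
    """Median-split marker prognosis with Kaplan-Meier curves and log-rank tests.

    ``single``: high vs low on ``marker_a``.  ``combined``: the four
    high/low combinations of ``marker_a`` and ``marker_b``, with (i) the
    overall multi-group test and (ii) the two-group contrast
    A-high&B-high vs A-high&B-low reported separately.  Median cut-points are
    computed over the samples with survival data.  Empty or degenerate
    contrasts are skipped with a logged reason; the others proceed.
    """
    if scheme not in ("single", "combined"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "combined" and marker_b is None:
        raise ValueError("combined scheme requires marker_b")

    meta = [m for m in metadata if m.survival_months is not None]
    if len(meta) < min_samples:
        raise ValueError(
            f"only {len(meta)} samples with survival data; floor is {min_samples}"
        )
    ids = [m.sample_id for m in meta]
    months = np.array([m.survival_months for m in meta])
    event = np.array([m.event for m in meta])
    months, event = _apply_horizon(months, event, horizon)

    markers = [(marker_a, "high_is_hit")]
    if marker_b is not None and marker_b != marker_a:
        markers.append((marker_b, "high_is_hit"))
    strat = dichotomize(cohort, markers, CutpointConfig("median"), scope=ids)
    calls = strat.calls

    strata: dict[str, str] = {}
    if scheme == "single":
        for s in ids:
            c = calls.loc[s, marker_a]
            if c != AT_CUTPOINT:
                strata[s] = "H" if c == HIT else "L"
    else:
        b_col = marker_b if marker_b in calls.columns else marker_a
        for s in ids:
            ca, cb = calls.loc[s, marker_a], calls.loc[s, b_col]
            if AT_CUTPOINT in (ca, cb):
                continue
            strata[s] = ("H" if ca == HIT else "L") + "/" + ("H" if cb == HIT else "L")

    pos = {s: i for i, s in enumerate(ids)}

    def group_data(label: str) -> tuple[np.ndarray, np.ndarray]:
        sel = [pos[s] for s, lab in strata.items() if lab == label]
        return months[sel], event[sel]

    label_set = sorted(set(strata.values()))
    curves = {
        lab: km_estimate(*group_data(lab)) for lab in label_set if group_data(lab)[0].size
    }

    tests: dict[str, LogRankResult] = {}
    skipped: dict[str, str] = {}

    def try_test(name: str, labs: list[str]) -> None:
        data = [group_data(lab) for lab in labs]
        empty = [lab for lab, (t, _) in zip(labs, data) if t.size == 0]
        if empty:
            skipped[name] = f"empty strata: {empty}"
            logger.warning("stratify_and_test: skipping %s (%s)", name, skipped[name])
            return
        try:
            tests[name] = logrank_test(data)
        except ValueError as err:
            skipped[name] = str(err)
            logger.warning("stratify_and_test: skipping %s (%s)", name, skipped[name])

    if scheme == "single":
        try_test("H_vs_L", ["H", "L"])
    else:
        if marker_b == marker_a:
            skipped["combined"] = "marker_b equals marker_a: combined contrast degenerate"
            logger.warning("stratify_and_test: %s", skipped["combined"])
            try_test("H_vs_L", label_set)  # collapses to H/H vs L/L
        else:
            present = [lab for lab in ("H/H", "H/L", "L/H", "L/L") if lab in label_set]
            if len(present) >= 2:
                try_test("all_strata", present)
            try_test("AhighBhigh_vs_AhighBlow", ["H/H", "H/L"])

    return StratifiedSurvival(
        scheme=scheme,
        strata=strata,
        curves=curves,
        tests=tests,
        skipped=skipped,
        cutpoints=strat.cutpoints,
    )


def marker_pvalue_table(
    cohort: ExpressionCohort,
    metadata: Iterable[SampleMetadata],
    markers: Sequence[str],
    combine_with: str | None = None,
    min_samples: int = 10,
    horizon: float | None = None,
) -> pd.DataFrame:
    """Per-marker prognosis p-values, alone and (optionally) anchored.

    For each marker: the single high-vs-low log-rank p; if ``combine_with``
    is given, also the A-high&B-high vs A-high&B-low p of the marker combined
    with the anchor — the table format used to ask whether adding the anchor
    improves a signature gene's prognostic separation.
    """
    meta = list(metadata)
    rows = []
    for marker in markers:
        single = stratify_and_test(
            cohort, meta, marker, scheme="single", min_samples=min_samples, horizon=horizon
        )
        row = {
            "marker": marker,
            "p_single": single.tests["H_vs_L"].p_value if "H_vs_L" in single.tests else np.nan,
        }
        if combine_with is not None and combine_with != marker:
            comb = stratify_and_test(
                cohort,
                meta,
                marker,
                marker_b=combine_with,
                scheme="combined",
                min_samples=min_samples,
                horizon=horizon,
            )
            t = comb.tests.get("AhighBhigh_vs_AhighBlow")
            row["p_combined"] = t.p_value if t is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
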