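"""Kaplan–Meier curves, log-rank comparison, and per-dataset / pooled odds ratios.

The product-limit estimator and the log-rank test delegate to lifelines;
subjects censored at an event time are counted as at risk for that event
(the standard convention).  Odds ratios use ad/bc with a Woolf (log-normal)
95% CI; any zero cell triggers the Haldane–Anscombe +0.5 correction on all
four cells.  The pooled estimate across datasets is Mantel–Haenszel (via
statsmodels); the displayed per-dataset weights are simply nᵢ/Σn, the share
of each dataset in the total cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = [
    "SurvivalCurve",
    "MetaORResult",
    "km_estimate",
    "logrank",
    "odds_ratio",
    "meta_or",
]


@dataclass
class SurvivalCurve:
    """A stepwise product-limit survival curve."""

    event_times: np.ndarray  # distinct times with ≥1 observed event, sorted
    at_risk: np.ndarray  # number at risk just before each event time
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray  # censoring times (marks)

    def s_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate for one group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival sample")
    if (t < 0).any():
        raise ValueError("negative survival time")
    if set(np.unique(e)) - {0, 1}:
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = np.array([kmf.survival_function_at_times(x).iloc[0] for x in event_times])
    return SurvivalCurve(
        event_times=event_times,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


def logrank(group1: tuple, group2: tuple) -> tuple[float, float]:
    """Two-group log-rank test: (χ² statistic, p from χ²₁).

    Each group is (times, events).  The statistic is (Σ(O−E))²/V with the
    hypergeometric variance at each distinct event time.
    """
    t1, e1 = (np.asarray(x) for x in group1)
    t2, e2 = (np.asarray(x) for x in group2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("each group needs at least one subject")
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def odds_ratio(table2x2, correction: str = "haldane") -> tuple[float, tuple[float, float]]:
    """(OR, Woolf 95% CI) for a 2×2 table [[a, b], [c, d]].

    With any zero cell and ``correction="haldane"``, 0.5 is added to all four
    cells before both the OR and its CI are computed.
    """
    tab = np.asarray(table2x2, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (tab < 0).any():
        raise ValueError("negative cell counts")
    if tab.sum() == 0:
        raise ValueError("all-zero table")
    a, b, c, d = tab.ravel()
    if correction == "haldane" and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif 0 in (b, c):
        raise ValueError("zero cell without correction gives an infinite OR")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi))


@dataclass
class MetaORResult:
    """Per-dataset and Mantel–Haenszel pooled odds ratios (forest-plot table)."""

    dataset_names: list[str]
    tables: list[np.ndarray]
    ors: list[float]
    cis: list[tuple[float, float]]
    weights: list[float]  # dataset n / total n
    pooled_or: float
    pooled_ci: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (name, o, ci[0], ci[1], w)
            for name, o, ci, w in zip(self.dataset_names, self.ors, self.cis, self.weights)
        ]
        rows.append(("pooled", self.pooled_or, self.pooled_ci[0], self.pooled_ci[1], 1.0))
        return pd.DataFrame(rows, columns=["dataset", "or", "ci_low", "ci_high", "weight"])


def meta_or(tables, names: list[str] | None = None) -> MetaORResult:
    """Pool 2×2 tables (event × predicted class) with Mantel–Haenszel.

    Per-dataset ORs/CIs use :func:`odds_ratio` (Haldane-corrected where
    needed); displayed weights are each dataset's share of the total cases.
    With a single table the pooled OR equals that table's OR.
    """
    tabs = [np.asarray(t, dtype=float) for t in tables]
    if not tabs:
        raise ValueError("need at least one table")
    names = names or [f"dataset{i + 1}" for i in range(len(tabs))]
    ns = [t.sum() for t in tabs]
    total = sum(ns)
    ors, cis = [], []
    for t in tabs:
        o, ci = odds_ratio(t)
        ors.append(o)
        cis.append(ci)
    if len(tabs) == 1:
        pooled, pooled_ci = ors[0], cis[0]
    else:
        st = StratifiedTable(np.stack(tabs, axis=-1))
        pooled = float(st.oddsratio_pooled)
        lo, hi = st.oddsratio_pooled_confint(alpha=0.05)
        pooled_ci = (float(lo), float(hi))
    return MetaORResult(
        dataset_names=names,
        tables=tabs,
        ors=ors,
        cis=cis,
        weights=[float(n / total) for n in ns],
        pooled_or=pooled,
        pooled_ci=pooled_ci,
    )
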