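"""Statistical analysis of the factorial simulation output.

Per-KPI univariate ANOVAs over the six layout factors and all fifteen
two-factor interactions (the factorial design is balanced, so the
sum-of-squares convention is immaterial; type-II is used and a warning
names it if the input is unbalanced). Significance is reported in the
three conventional tiers 0.001 / 0.01 / 0.05, matching how simulation
studies typeset their effect tables.

Cost-efficiency is analysed separately, since it mixes a response (the
throughput rate, the inverse of mean cycle time) with a design quantity
(layout cost): an ordinary least-squares regression of rate on cost plus
an isocost scan picking the best layout at each fixed cost.

Best layouts are selected per stakeholder with an explicit rule:
lexicographic on the stakeholder's primary score with a one-standard-
error tolerance, ties broken by cost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kpi import KPI_COLUMNS

__all__ = [
    "FACTORS",
    "AnovaResult",
    "anova_kpis",
    "significance_tier",
    "qq_normality",
    "CostEfficiencyPoint",
    "cost_efficiency",
    "best_layouts",
    "best_factor_combinations",
]

FACTORS = [
    "queue_policy",
    "physician_timetable",
    "hb_placement",
    "n_nurses",
    "n_clerks",
    "n_beds",
]

#: Direction each KPI is optimized in (for best-combination tables).
KPI_DIRECTION = {
    "cycle_time_avg": "min", "cycle_time_booked_avg": "min",
    "cycle_time_unbooked_avg": "min",
    "queue_time_avg": "min", "queue_time_booked_avg": "min",
    "queue_time_unbooked_avg": "min",
    "util_nurse": "max", "util_clerk": "max", "util_bed": "max",
    "util_physician": "min",
    "capacity_k1": "max", "capacity_k2": "max", "capacity_k3": "max",
    "last_exit_k1": "min", "last_exit_k2": "min", "last_exit_k3": "min",
}


def significance_tier(p: float) -> str:
    """Map a p-value to the conventional 0.001 / 0.01 / 0.05 / ns tiers."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p < 0.001:
        return "0.001"
    if p < 0.01:
        return "0.01"
    if p < 0.05:
        return "0.05"
    return "ns"


@dataclass
class AnovaResult:
    """Effect p-values and tiers for one KPI."""

    kpi: str
    p_values: Dict[str, float]  # effect name -> p
    tiers: Dict[str, str]

    def significant(self, level: float = 0.05) -> List[str]:
        return [e for e, p in self.p_values.items() if p < level]


def _is_balanced(results: pd.DataFrame) -> bool:
    counts = results.groupby(FACTORS, observed=True).size()
    return counts.nunique() == 1


def anova_kpis(
    results: pd.DataFrame, kpis: Optional[Sequence[str]] = None
) -> Dict[str, AnovaResult]:
    """Per-KPI ANOVA with six main effects and all two-factor interactions.

    ``results`` is the long table from :func:`donorflow.experiments.run_plan`
    (one row per layout x replication, factor columns included).
    Cost-efficiency is not a response here — it is handled by
    :func:`cost_efficiency`.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not _is_balanced(results):
        warnings.warn(
            "unbalanced design: p-values use type-II sums of squares",
            stacklevel=2,
        )
    terms = [f"C({f})" for f in FACTORS]
    inter = [
        f"C({a}):C({b})"
        for i, a in enumerate(FACTORS)
        for b in FACTORS[i + 1:]
    ]
    rhs = " + ".join(terms + inter)
    kpis = list(kpis) if kpis is not None else [
        k for k in KPI_COLUMNS if k in results.columns
    ]
    out: Dict[str, AnovaResult] = {}
    for kpi in kpis:
        data = results[FACTORS + [kpi]].dropna()
        model = smf.ols(f"{kpi} ~ {rhs}", data=data).fit()
        table = sm.stats.anova_lm(model, typ=2)
        pvals = {}
        for effect, row in table.iterrows():
            if effect == "Residual":
                continue
            name = effect.replace("C(", "").replace(")", "")
            pvals[name] = float(row["PR(>F)"])
        out[kpi] = AnovaResult(
            kpi=kpi,
            p_values=pvals,
            tiers={e: significance_tier(p) for e, p in pvals.items()},
        )
    return out


def anova_table(anovas: Dict[str, AnovaResult]) -> pd.DataFrame:
    """Wide effect table: rows = KPIs, columns = effects, cells = p-values."""
    effects: List[str] = []
    for res in anovas.values():
        for e in res.p_values:
            if e not in effects:
                effects.append(e)
    return pd.DataFrame(
        {e: [anovas[k].p_values.get(e, math.nan) for k in anovas] for e in effects},
        index=list(anovas),
    )


# ---------------------------------------------------------------------------
# Normality diagnostics
# ---------------------------------------------------------------------------

@dataclass
class QQSummary:
    """Ordered-sample vs normal-quantile pairs and their correlation."""

    theoretical: np.ndarray
    ordered: np.ndarray
    correlation: float
    degenerate: bool = False


def qq_normality(samples: Sequence[float]) -> QQSummary:
    """Quantile-quantile normality diagnostic.

    Returns the (normal quantile, ordered sample) pairs a q-q plot would
    show, plus the probability-plot correlation coefficient: values near
    1 are consistent with normality, heavy tails pull the coefficient
    down. A constant sample is flagged degenerate.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 10:
        raise ValueError("q-q diagnostic needs at least 10 samples")
    if np.ptp(x) == 0.0:
        return QQSummary(np.array([]), np.array([]), math.nan, degenerate=True)
    (osm, osr), (slope, intercept, r) = stats.probplot(x, dist="norm")
    return QQSummary(theoretical=osm, ordered=osr, correlation=float(r))


# ---------------------------------------------------------------------------
# Cost-efficiency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostEfficiencyPoint:
    """One layout on the cost / throughput plane."""

    layout: str
    cost: float
    rate: float  # donors per minute = 1 / mean cycle time

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.rate <= 0:
            raise ValueError("cost and rate must be positive")


@dataclass
class CostEfficiencyResult:
    slope: float
    intercept: float
    r_squared: float
    best_per_cost: Dict[float, str]  # cost level -> best layout name


def cost_efficiency(points: Sequence[CostEfficiencyPoint]) -> CostEfficiencyResult:
    """OLS of throughput rate on cost, plus the isocost best layouts.

    Needs at least three distinct cost levels for the regression to be
    meaningful; at each cost level the layout with the highest mean rate
    is the isocost winner.
    """
    costs = np.array([p.cost for p in points])
    rates = np.array([p.rate for p in points])
    if len(set(costs.tolist())) < 3:
        raise ValueError("cost-efficiency regression needs >= 3 distinct cost levels")
    fit = stats.linregress(costs, rates)
    best: Dict[float, str] = {}
    for level in sorted(set(costs.tolist())):
        group = [p for p in points if p.cost == level]
        best[level] = max(group, key=lambda p: (p.rate, p.layout)).layout
    return CostEfficiencyResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        best_per_cost=best,
    )


def efficiency_points(results: pd.DataFrame) -> List[CostEfficiencyPoint]:
    """Mean throughput per layout, paired with its cost."""
    grouped = results.groupby("layout", observed=True).agg(
        rate=("throughput_rate", "mean"), cost=("cost", "first")
    )
    return [
        CostEfficiencyPoint(layout=name, cost=float(row.cost), rate=float(row.rate))
        for name, row in grouped.iterrows()
    ]


# ---------------------------------------------------------------------------
# Best-layout selection
# ---------------------------------------------------------------------------

def _lexi_best(scores: pd.DataFrame, higher_is_better: bool) -> str:
    """Pick the best layout: primary score with a one-SE tolerance, then cost.

    Layouts whose mean score is within one standard error of the best are
    considered tied; the cheapest of them wins, then name order.
    """
    sign = 1.0 if higher_is_better else -1.0
    s = scores.assign(signed=sign * scores["score"])
    top = s["signed"].max()
    se = s.loc[s["signed"].idxmax(), "se"]
    tol = 0.0 if math.isnan(se) else se
    tied = s[s["signed"] >= top - tol]
    tied = tied.sort_values(["cost", "layout"])
    return str(tied.iloc[0]["layout"])


def best_layouts(results: pd.DataFrame) -> Dict[str, str]:
    """Best layout per stakeholder.

    * donors — minimize mean cycle time (cost is ignored);
    * resources — maximize the mean utilization of nurses, clerks and
      beds minus the physicians' utilization (saturate the variable
      resources, desaturate the scarce physicians);
    * management — maximize cost-efficiency, throughput rate per CU.
    """
    g = results.groupby("layout", observed=True)
    n = g.size()

    def table(series_mean, series_se, cost):
        return pd.DataFrame(
            {
                "layout": series_mean.index,
                "score": series_mean.values,
                "se": series_se.values,
                "cost": cost.values,
            }
        )

    cost = g["cost"].first()

    cyc_m = g["cycle_time_avg"].mean()
    cyc_se = g["cycle_time_avg"].std(ddof=1) / np.sqrt(n)
    donors = _lexi_best(table(cyc_m, cyc_se, cost), higher_is_better=False)

    res_score = results[["util_nurse", "util_clerk", "util_bed"]].mean(axis=1) - results[
        "util_physician"
    ]
    res_df = results.assign(_res=res_score).groupby("layout", observed=True)
    res_m = res_df["_res"].mean()
    res_se = res_df["_res"].std(ddof=1) / np.sqrt(n)
    resources = _lexi_best(table(res_m, res_se, cost), higher_is_better=True)

    eff = results["throughput_rate"] / results["cost"]
    eff_df = results.assign(_eff=eff).groupby("layout", observed=True)
    eff_m = eff_df["_eff"].mean()
    eff_se = eff_df["_eff"].std(ddof=1) / np.sqrt(n)
    management = _lexi_best(table(eff_m, eff_se, cost), higher_is_better=True)

    return {"donors": donors, "resources": resources, "management": management}


def best_factor_combinations(
    results: pd.DataFrame,
    anovas: Dict[str, AnovaResult],
    level: float = 0.05,
) -> pd.DataFrame:
    """Best level of each *significant* factor for each KPI.

    Rows = KPIs, columns = factors; a cell holds the factor level with
    the best mean response (direction per KPI), blank where the factor's
    main effect is not significant at ``level``. Interactions are not
    tabulated.
    """
    rows = {}
    for kpi, res in anovas.items():
        direction = KPI_DIRECTION.get(kpi, "min")
        row = {}
        for f in FACTORS:
            p = res.p_values.get(f, math.nan)
            if math.isnan(p) or p >= level:
                row[f] = ""
                continue
            means = results.groupby(f, observed=True)[kpi].mean()
            best = means.idxmin() if direction == "min" else means.idxmax()
            row[f] = str(best)
        rows[kpi] = row
    return pd.DataFrame(rows).T
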