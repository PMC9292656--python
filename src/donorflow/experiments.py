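"""Factorial experiment plan, CRN replications and model validation.

The experimental plan crosses six layout factors — queue policy (2),
physician timetable (2), haemoglobin placement (3) and twelve
nurse/clerk/bed combinations — into 144 layouts, each replicated n times
(n=30 in the full plan, 4,320 runs). Replications use common random
numbers: within a replication every layout consumes identical arrival
realizations, service-time draws and deferral draws, because all streams
are keyed by (replication, donor, activity) and never by layout.

Validation follows standard simulation practice: replicate the baseline
layout, test the mean donor cycle time against the centre's reported
true value with a two-sided one-sample t-test, and — because failing to
reject is weak evidence on its own — compute the sample critical
difference ``delta = |xbar - mu| / s`` and the type-II error of the test
at that difference from the noncentral-t power function, inverting it
for the replication count that brings the type-II error under a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (
    CODE_RESOURCES,
    DeferralRates,
    LayoutConfig,
    run_day,
)
from .distributions import ProcessTimeCatalog, default_catalog
from .kpi import CostModel, compute_kpis
from .schedule import BehaviourParams, DaySchedule, realize_arrivals
from .streams import StreamFamily

__all__ = [
    "enumerate_layouts",
    "ExperimentPlan",
    "run_plan",
    "run_replications",
    "ValidationSummary",
    "validate_baseline",
    "power_one_sample_t",
    "required_sample_size",
]


def enumerate_layouts() -> List[LayoutConfig]:
    """All 144 layouts in deterministic order.

    Order: queue policy (FIFO, PRTY) x timetable (1, 2) x haemoglobin
    placement (W, A, B) x resource code (01..12).
    """
    layouts = []
    for policy in ("FIFO", "PRTY"):
        for timetable in (1, 2):
            for hb in ("W", "A", "B"):
                for code in sorted(CODE_RESOURCES):
                    nurses, clerks, beds = CODE_RESOURCES[code]
                    layouts.append(
                        LayoutConfig(policy, timetable, hb, nurses, clerks, beds)
                    )
    return layouts


@dataclass(frozen=True)
class ExperimentPlan:
    """A set of layouts, a replication count and a master seed."""

    layouts: Sequence[LayoutConfig] = field(default_factory=enumerate_layouts)
    replications: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("need at least one replication")
        names = [l.name for l in self.layouts]
        if len(set(names)) != len(names):
            raise ValueError("plan contains duplicate layouts")

    @property
    def total_runs(self) -> int:
        return len(self.layouts) * self.replications


def run_replications(
    layout: LayoutConfig,
    day: DaySchedule,
    *,
    replications: int,
    master_seed: int = 0,
    catalog: Optional[ProcessTimeCatalog] = None,
    rates: DeferralRates = DeferralRates(),
    behaviour: BehaviourParams = BehaviourParams(),
    cost_model: CostModel = CostModel(),
) -> pd.DataFrame:
    """Replicate one layout; one flat KPI row per replication."""
    catalog = catalog or default_catalog()
    rows = []
    for j in range(replications):
        streams = StreamFamily(master_seed, replication=j)
        arrivals = realize_arrivals(day, behaviour, streams)
        log = run_day(layout, arrivals, catalog, rates, streams, day)
        row = compute_kpis(log, cost_model).flat()
        row["replication"] = j
        rows.append(row)
    return pd.DataFrame(rows)


def run_plan(
    plan: ExperimentPlan,
    day: DaySchedule,
    *,
    catalog: Optional[ProcessTimeCatalog] = None,
    rates: DeferralRates = DeferralRates(),
    behaviour: BehaviourParams = BehaviourParams(),
    cost_model: CostModel = CostModel(),
) -> pd.DataFrame:
    """Run the full plan with common random numbers across layouts.

    Returns one row per (layout, replication) with all flat KPI columns
    plus the six factor columns. Arrival realizations and per-donor draws
    are generated once per replication and shared by every layout.
    """
    from .engine import _predraw

    catalog = catalog or default_catalog()
    rows = []
    for j in range(plan.replications):
        streams = StreamFamily(plan.master_seed, replication=j)
        arrivals = realize_arrivals(day, behaviour, streams)
        draws = _predraw(arrivals, catalog, rates, streams)
        for layout in plan.layouts:
            log = run_day(layout, arrivals, catalog, rates, streams, day, draws=draws)
            row = compute_kpis(log, cost_model).flat()
            row["replication"] = j
            row["queue_policy"] = layout.queue_policy
            row["physician_timetable"] = layout.physician_timetable
            row["hb_placement"] = layout.hb_placement
            row["n_nurses"] = layout.n_nurses
            row["n_clerks"] = layout.n_clerks
            row["n_beds"] = layout.n_beds
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Validation statistics
# ---------------------------------------------------------------------------

def power_one_sample_t(delta: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided one-sample t-test at standardized effect ``delta``.

    ``delta`` is the difference between true and hypothesized mean in
    units of the population standard deviation. Computed from the
    noncentral-t distribution, not from a printed operating-characteristic
    chart.
    """
    if n < 2:
        return float("nan")
    df = n - 1
    nc = delta * math.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - (stats.nct.cdf(tcrit, df, nc) - stats.nct.cdf(-tcrit, df, nc))
    )


def required_sample_size(
    delta: float, alpha: float = 0.05, beta_target: float = 0.05, n_max: int = 10_000
) -> int:
    """Smallest n whose two-sided t-test has type-II error <= ``beta_target``."""
    for n in range(2, n_max + 1):
        if 1.0 - power_one_sample_t(delta, n, alpha) <= beta_target:
            return n
    raise ValueError(f"no n <= {n_max} reaches beta <= {beta_target} at delta={delta}")


@dataclass(frozen=True)
class ValidationSummary:
    """Outcome of validating simulated cycle time against a known mean."""

    sample_mean: float
    sample_sd: float
    n: int
    reference_mean: float
    alpha: float
    t_statistic: float
    p_value: float
    reject: bool
    critical_difference: float  # |xbar - mu| / s
    beta_at_delta: float  # type-II error of the test at that difference
    n_required: int  # replications needed for beta <= beta_target
    degenerate: bool = False  # zero sample variance: t undefined


def validate_baseline(
    samples: Sequence[float],
    mu: float,
    alpha: float = 0.05,
    beta_target: float = 0.05,
) -> ValidationSummary:
    """Validate replicated mean cycle times against the true mean ``mu``."""
    x = np.asarray(list(samples), dtype=float)
    if x.size < 2:
        raise ValueError("validation needs at least 2 replications")
    return validate_from_summary(
        float(x.mean()), float(x.std(ddof=1)), int(x.size), mu, alpha, beta_target
    )


def validate_from_summary(
    sample_mean: float,
    sample_sd: float,
    n: int,
    mu: float,
    alpha: float = 0.05,
    beta_target: float = 0.05,
) -> ValidationSummary:
    """Same validation from summary statistics instead of raw samples."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if sample_sd == 0.0:
        return ValidationSummary(
            sample_mean, 0.0, n, mu, alpha,
            t_statistic=float("nan"), p_value=float("nan"), reject=False,
            critical_difference=0.0, beta_at_delta=float("nan"), n_required=n,
            degenerate=True,
        )
    t_stat = (sample_mean - mu) / (sample_sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
    delta = abs(sample_mean - mu) / sample_sd
    beta = 1.0 - power_one_sample_t(delta, n, alpha)
    n_req = required_sample_size(delta, alpha, beta_target) if delta > 0 else n
    return ValidationSummary(
        sample_mean, sample_sd, n, mu, alpha,
        t_statistic=float(t_stat), p_value=float(p), reject=bool(p < alpha),
        critical_difference=float(delta), beta_at_delta=float(beta),
        n_required=max(int(n_req), 2), degenerate=False,
    )
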