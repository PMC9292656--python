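"""Key performance indicators computed from one day's event log.

Three stakeholder views:

* donors — cycle time (arrival to exit, *including* the canteen
  refreshment, which is part of the perceived time in the centre) and
  total queue time, overall and stratified by booked/unbooked;
* resources — utilization of physicians, nurses, clerks, beds and, where
  present, the dedicated haemoglobin-station nurse, as busy minutes
  within opening hours over scheduled availability;
* management — per-period physician capacity actually used, per-period
  exit time from consultation of the last donor, layout cost in cost
  units (CU) and the throughput rate (inverse mean cycle time).

Costs cover only the resources that vary with the layout: clerk 5 CU,
nurse 10 CU, bed 1 CU per workday (1 CU is roughly 20 euros at the
reference centre); physicians are a fixed cost and excluded. Layouts with
a separate haemoglobin station (A/B) pay for one extra dedicated nurse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .engine import EventLog, LayoutConfig, PhysicianTimetable

__all__ = [
    "CostModel",
    "KpiReport",
    "Stats",
    "cycle_and_queue_times",
    "utilization",
    "period_capacity_and_last_exit",
    "layout_cost",
    "compute_kpis",
    "KPI_COLUMNS",
]


@dataclass(frozen=True)
class CostModel:
    """Per-workday cost (CU) of the variable resources."""

    clerk: float = 5.0
    nurse: float = 10.0
    bed: float = 1.0

    def __post_init__(self) -> None:
        if min(self.clerk, self.nurse, self.bed) < 0:
            raise ValueError("costs must be >= 0")


@dataclass(frozen=True)
class Stats:
    """min / avg / max triple; NaN when the stratum is empty."""

    min: float = math.nan
    avg: float = math.nan
    max: float = math.nan
    n: int = 0

    @classmethod
    def of(cls, values: List[float]) -> "Stats":
        if not values:
            return cls()
        arr = np.asarray(values, dtype=float)
        return cls(float(arr.min()), float(arr.mean()), float(arr.max()), len(values))

    @property
    def defined(self) -> bool:
        return self.n > 0


def cycle_and_queue_times(log: EventLog) -> Dict[str, Stats]:
    """Cycle and queue time statistics, overall and per donor type.

    Cycle time is defined for completed donors only (deferred donors do
    not traverse the whole system); queue time sums every waiting
    interval a donor experienced — registration, haemoglobin station,
    consultation, donation-room entry (bed and nurse) and the wait for a
    nurse at post-setup. Empty strata are reported as undefined (NaN),
    never as zero.
    """
    out: Dict[str, Stats] = {}
    completed = log.completed()
    strata = {
        "": completed,
        "_booked": [r for r in completed if r.donor_type == "booked"],
        "_unbooked": [r for r in completed if r.donor_type == "unbooked"],
    }
    for suffix, recs in strata.items():
        out[f"cycle_time{suffix}"] = Stats.of([r.cycle_time for r in recs])
        out[f"queue_time{suffix}"] = Stats.of([r.queue_time for r in recs])
    # Consultation queue alone: the system's bottleneck queue, reported
    # separately for the accumulation analysis. All donors who reached it.
    cons_waits = [
        r.waits["consultation"] for r in log.donors if "consultation" in r.waits
    ]
    out["consultation_queue_time"] = Stats.of(cons_waits)
    return out


def _availability(log: EventLog) -> Dict[str, float]:
    day = log.day
    open_minutes = day.closing - day.opening
    timetable = PhysicianTimetable(log.layout.physician_timetable, day)
    avail = {
        "physician": timetable.scheduled_minutes(),
        "clerk": log.layout.n_clerks * open_minutes,
        "nurse": log.layout.n_nurses * open_minutes,
        "bed": log.layout.n_beds * open_minutes,
    }
    if log.layout.has_hb_station:
        avail["hb_nurse"] = open_minutes
    return avail


def utilization(log: EventLog) -> Dict[str, float]:
    """Busy fraction per resource kind.

    Only busy minutes falling within opening hours count (overtime past
    closing is excluded from the numerator), over the scheduled
    availability: physicians 3x450 min/day at the defaults, every other
    resource count x opening span (staff other than physicians are
    present from first opening to closure).
    """
    avail = _availability(log)
    busy = {k: 0.0 for k in avail}
    lo, hi = log.day.opening, log.day.closing
    for b in log.busy:
        if b.resource in busy:
            busy[b.resource] += max(0.0, min(b.end, hi) - max(b.start, lo))
    return {k: busy[k] / avail[k] for k in avail}


def period_capacity_and_last_exit(
    log: EventLog, by: str = "arrival"
) -> Dict[int, Dict[str, float]]:
    """Per-period physician capacity used and last consultation exit.

    ``by="arrival"`` (default) attributes a donor's consultation minutes
    to the period the donor *arrived* in — the period the upstream
    scheduler booked them into — so the KPI measures how well each
    scheduling period's workload fits its nominal capacity.
    ``by="service"`` attributes by the period the consultation started
    in. Used capacity under layout W includes the haemoglobin minutes
    (they occupy the physician); under A/B it does not.
    """
    if by not in ("arrival", "service"):
        raise ValueError("by must be 'arrival' or 'service'")
    out: Dict[int, Dict[str, float]] = {
        p.index: {"used_capacity": 0.0, "last_exit": math.nan} for p in log.day.periods
    }
    bounds = {p.index: (p.start, p.end) for p in log.day.periods}
    for r in log.donors:
        if r.cons_start is None:
            continue
        if by == "arrival":
            k = r.period
        else:
            k = next(
                (i for i, (s, e) in bounds.items() if s <= r.cons_start < e),
                log.day.periods[-1].index,
            )
        out[k]["used_capacity"] += r.cons_end - r.cons_start
        prev = out[k]["last_exit"]
        out[k]["last_exit"] = (
            r.cons_end if math.isnan(prev) else max(prev, r.cons_end)
        )
    return out


def layout_cost(layout: LayoutConfig, cost_model: CostModel = CostModel()) -> float:
    """Daily variable cost of a layout in CU.

    A separate haemoglobin station (placement A or B) adds one dedicated
    nurse on top of the donation-room pool.
    """
    cost = (
        layout.n_clerks * cost_model.clerk
        + layout.n_nurses * cost_model.nurse
        + layout.n_beds * cost_model.bed
    )
    if layout.has_hb_station:
        cost += cost_model.nurse
    return cost


@dataclass
class KpiReport:
    """All indicators for one simulated day."""

    layout_name: str
    times: Dict[str, Stats]
    utilizations: Dict[str, float]
    periods: Dict[int, Dict[str, float]]
    cost: float
    n_arrivals: int = 0
    n_completed: int = 0
    n_deferred_hb: int = 0
    n_deferred_consultation: int = 0

    @property
    def throughput_rate(self) -> float:
        """Donors per minute: the inverse of the mean cycle time."""
        avg = self.times["cycle_time"].avg
        return 1.0 / avg if avg and not math.isnan(avg) else math.nan

    def flat(self) -> Dict[str, float]:
        """One flat row of scalars (for tabular experiment output)."""
        row: Dict[str, float] = {"layout": self.layout_name, "cost": self.cost}
        for key, st in self.times.items():
            row[f"{key}_min"] = st.min
            row[f"{key}_avg"] = st.avg
            row[f"{key}_max"] = st.max
        for res, u in self.utilizations.items():
            row[f"util_{res}"] = u
        for k, vals in self.periods.items():
            row[f"capacity_k{k}"] = vals["used_capacity"]
            row[f"last_exit_k{k}"] = vals["last_exit"]
        row["throughput_rate"] = self.throughput_rate
        row["n_arrivals"] = self.n_arrivals
        row["n_completed"] = self.n_completed
        row["n_deferred_hb"] = self.n_deferred_hb
        row["n_deferred_consultation"] = self.n_deferred_consultation
        return row


#: Response columns used by the factorial analysis.
KPI_COLUMNS = [
    "cycle_time_avg", "cycle_time_booked_avg", "cycle_time_unbooked_avg",
    "queue_time_avg", "queue_time_booked_avg", "queue_time_unbooked_avg",
    "util_nurse", "util_clerk", "util_bed", "util_physician",
    "capacity_k1", "capacity_k2", "capacity_k3",
    "last_exit_k1", "last_exit_k2", "last_exit_k3",
]


def compute_kpis(
    log: EventLog,
    cost_model: CostModel = CostModel(),
    attribution: str = "arrival",
) -> KpiReport:
    """All KPIs for one event log."""
    donors = log.donors
    return KpiReport(
        layout_name=log.layout.name,
        times=cycle_and_queue_times(log),
        utilizations=utilization(log),
        periods=period_capacity_and_last_exit(log, by=attribution),
        cost=layout_cost(log.layout, cost_model),
        n_arrivals=len(donors),
        n_completed=sum(r.outcome == "completed" for r in donors),
        n_deferred_hb=sum(r.outcome == "deferred_hb" for r in donors),
        n_deferred_consultation=sum(
            r.outcome == "deferred_consultation" for r in donors
        ),
    )
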