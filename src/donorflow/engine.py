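"""Event-driven simulation of one day in a whole-blood collection centre.

The engine advances an event calendar (a heap of timestamped events) with
no fixed tick. Donors flow through:

    arrival -> registration (clerk) -> [haemoglobin station, layout B]
            -> consultation (physician) -> [haemoglobin station, layout A]
            -> donation room (bed + nurse pre-setup, unattended phlebotomy,
               nurse post-setup, rest on bed) -> canteen (unlimited) -> exit

Layout levers (:class:`LayoutConfig`):

* consultation queue discipline — FIFO, or priority to booked donors;
* part-time physician placement — the nominal 450 physician-minutes per
  two-hour period correspond to 3.75 physicians: three work the full
  period and a fourth works 90 minutes, placed at the period start
  (timetable 1) or end (timetable 2);
* haemoglobin testing within the consultation (W), at a dedicated
  station after it (A), or before it (B) — A/B add a station staffed by
  one dedicated nurse outside the donation-room pool;
* counts of nurses, clerks and beds.

Donors can be deferred (temporarily rejected) at the haemoglobin test or
at the consultation; deferred donors leave immediately. All stochastic
quantities — service times and deferral outcomes — are drawn once per
donor when the run starts, from streams keyed by (donor, activity), so
common random numbers hold exactly across layouts.

The centre admits arrivals only during opening hours, but the simulation
runs until the last donor leaves, even past closing; the closing staffing
level keeps serving the residual queue (overtime).
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .distributions import ProcessTimeCatalog, bernoulli, sample
from .schedule import ArrivalEvent, DaySchedule
from .streams import StreamFamily

__all__ = [
    "LayoutConfig",
    "DeferralRates",
    "DonorRecord",
    "BusyInterval",
    "EventLog",
    "PhysicianTimetable",
    "run_day",
    "select_next",
]

QUEUE_POLICIES = ("FIFO", "PRTY")
HB_PLACEMENTS = ("W", "A", "B")

#: Table of resource-combination codes: (nurses, clerks, beds) -> "01".."12"
RESOURCE_CODES = {
    (2, 1, 5): "01", (2, 1, 6): "02", (2, 1, 7): "03",
    (2, 2, 5): "04", (2, 2, 6): "05", (2, 2, 7): "06",
    (3, 1, 5): "07", (3, 1, 6): "08", (3, 1, 7): "09",
    (3, 2, 5): "10", (3, 2, 6): "11", (3, 2, 7): "12",
}
CODE_RESOURCES = {v: k for k, v in RESOURCE_CODES.items()}


@dataclass(frozen=True)
class LayoutConfig:
    """One of the 144 experimental layouts of the centre."""

    queue_policy: str = "FIFO"
    physician_timetable: int = 1
    hb_placement: str = "W"
    n_nurses: int = 2
    n_clerks: int = 1
    n_beds: int = 5

    def __post_init__(self) -> None:
        if self.queue_policy not in QUEUE_POLICIES:
            raise ValueError(f"queue_policy must be FIFO or PRTY, got {self.queue_policy!r}")
        if self.physician_timetable not in (1, 2):
            raise ValueError("physician_timetable must be 1 (start) or 2 (end)")
        if self.hb_placement not in HB_PLACEMENTS:
            raise ValueError("hb_placement must be W, A or B")
        if min(self.n_nurses, self.n_clerks, self.n_beds) < 1:
            raise ValueError("resource counts must be >= 1")

    @property
    def resource_code(self) -> Optional[str]:
        """Two-digit code for the 12 experimental resource combinations;
        None for counts outside the experimental levels."""
        return RESOURCE_CODES.get((self.n_nurses, self.n_clerks, self.n_beds))

    @property
    def name(self) -> str:
        code = self.resource_code
        if code is None:  # outside the factorial levels: spell counts out
            code = f"n{self.n_nurses}c{self.n_clerks}b{self.n_beds}"
        return (
            f"{self.queue_policy}-{self.physician_timetable}-"
            f"{self.hb_placement}-{code}"
        )

    @classmethod
    def from_name(cls, name: str) -> "LayoutConfig":
        policy, timetable, hb, code = name.split("-")
        nurses, clerks, beds = CODE_RESOURCES[code]
        return cls(policy, int(timetable), hb, nurses, clerks, beds)

    @property
    def has_hb_station(self) -> bool:
        return self.hb_placement in ("A", "B")


@dataclass(frozen=True)
class DeferralRates:
    """Bernoulli deferral probabilities at the clinical gates.

    Walk-in donors are deferred at the consultation far more often than
    booked donors (who were pre-screened at reservation); the defaults
    give combined acceptance rates of 99% (booked) and 95% (unbooked).
    """

    p_consultation_booked: float = 5.03e-3
    p_consultation_unbooked: float = 4.523e-2
    p_haemoglobin: float = 5e-3

    def __post_init__(self) -> None:
        for p in (self.p_consultation_booked, self.p_consultation_unbooked, self.p_haemoglobin):
            if not 0.0 <= p <= 1.0:
                raise ValueError("deferral rates must lie in [0, 1]")

    def acceptance_rate(self, donor_type: str) -> float:
        """Combined probability that a donor passes both clinical gates."""
        p_cons = (
            self.p_consultation_booked
            if donor_type == "booked"
            else self.p_consultation_unbooked
        )
        return (1.0 - p_cons) * (1.0 - self.p_haemoglobin)


class PhysicianTimetable:
    """Step function of physicians on duty over the day.

    Three physicians cover each full period; a fourth covers 90 of the
    120 minutes, at the period start (config 1) or end (config 2), so the
    integral over every period is the nominal 450 physician-minutes.
    After closing, the staffing of the last instant before closure is
    retained until the floor drains (overtime); before opening the count
    is zero.
    """

    def __init__(self, config: int, day: DaySchedule):
        if config not in (1, 2):
            raise ValueError("timetable config must be 1 or 2")
        self.config = config
        self.periods = [(p.start, p.end) for p in day.periods]
        self.opening = day.opening
        self.closing = day.closing

    def fourth_on(self, t: float) -> bool:
        """Is the part-time physician on duty at clock-minute ``t``?"""
        for start, end in self.periods:
            if start <= t < end:
                if self.config == 1:
                    return t < start + 90.0
                return t >= start + 30.0
        if t >= self.closing:  # overtime: keep the closing staffing
            return self.config == 2
        return False

    def on_duty(self, t: float) -> int:
        if t < self.opening:
            return 0
        return 3 + (1 if self.fourth_on(t) else 0)

    def change_points(self) -> List[float]:
        """Times where the on-duty count may step (for dispatcher wake-ups)."""
        pts = []
        for start, end in self.periods:
            pts.extend([start, start + 30.0, start + 90.0, end])
        return sorted(set(pts))

    def scheduled_minutes(self) -> float:
        """Total planned physician-minutes over the day (e.g. 3 x 450)."""
        return sum((end - start) * 3 + 90.0 for start, end in self.periods)


@dataclass
class DonorRecord:
    """Timestamps and accounting for one donor's path through the centre.

    Timestamps are clock-minutes; ``None`` means the stage was not
    reached (deferred donors have no downstream timestamps) or does not
    exist in the layout (no separate haemoglobin stage under W).
    """

    donor_id: str
    donor_type: str
    arrival: float
    period: int
    outcome: Optional[str] = None  # completed | deferred_hb | deferred_consultation
    reg_start: Optional[float] = None
    reg_end: Optional[float] = None
    hb_start: Optional[float] = None
    hb_end: Optional[float] = None
    cons_start: Optional[float] = None
    cons_end: Optional[float] = None
    bed_assigned: Optional[float] = None  # = pre-setup start
    phleb_start: Optional[float] = None
    phleb_end: Optional[float] = None
    post_start: Optional[float] = None
    post_end: Optional[float] = None
    rest_end: Optional[float] = None
    exit: Optional[float] = None
    waits: Dict[str, float] = field(default_factory=dict)
    services: Dict[str, float] = field(default_factory=dict)

    @property
    def cycle_time(self) -> Optional[float]:
        if self.outcome != "completed":
            return None
        return self.exit - self.arrival

    @property
    def queue_time(self) -> float:
        return sum(self.waits.values())

    @property
    def service_time(self) -> float:
        return sum(self.services.values())

    def timestamps(self) -> List[float]:
        """Realized timestamps in path order (for monotonicity checks)."""
        seq = [
            self.arrival, self.reg_start, self.reg_end, self.hb_start, self.hb_end,
            self.cons_start, self.cons_end, self.bed_assigned, self.phleb_start,
            self.phleb_end, self.post_start, self.post_end, self.rest_end, self.exit,
        ]
        # hb stage position depends on layout; sort-insensitive check is
        # done by the caller where needed. For A-placement hb follows the
        # consultation, so rebuild in realized order:
        if self.hb_start is not None and self.cons_end is not None and self.hb_start >= self.cons_end:
            seq = [
                self.arrival, self.reg_start, self.reg_end, self.cons_start,
                self.cons_end, self.hb_start, self.hb_end, self.bed_assigned,
                self.phleb_start, self.phleb_end, self.post_start, self.post_end,
                self.rest_end, self.exit,
            ]
        return [t for t in seq if t is not None]


@dataclass(frozen=True)
class BusyInterval:
    """One continuous occupation of one resource unit."""

    resource: str  # clerk | physician | nurse | hb_nurse | bed
    unit: int
    start: float
    end: float
    activity: str
    donor_id: str


@dataclass
class EventLog:
    """Full trace of one simulated day."""

    layout: LayoutConfig
    day: DaySchedule
    records: Dict[str, DonorRecord] = field(default_factory=dict)
    busy: List[BusyInterval] = field(default_factory=list)

    @property
    def donors(self) -> List[DonorRecord]:
        return list(self.records.values())

    def completed(self) -> List[DonorRecord]:
        return [r for r in self.donors if r.outcome == "completed"]

    def to_frame(self):
        """Donor records as a pandas DataFrame (one row per donor)."""
        import pandas as pd

        cols = [
            "donor_id", "donor_type", "period", "outcome", "arrival", "reg_start",
            "reg_end", "hb_start", "hb_end", "cons_start", "cons_end",
            "bed_assigned", "phleb_start", "phleb_end", "post_start", "post_end",
            "rest_end", "exit",
        ]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.donors]
        )

    def busy_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(b) for b in self.busy])


def select_next(
    queue: Sequence[Tuple[str, str, float]],
    policy: str,
    now: Optional[float] = None,
) -> str:
    """Pick the next donor from a consultation queue.

    ``queue`` holds ``(donor_id, donor_type, enqueue_time)`` triples.
    FIFO returns the earliest enqueued donor; PRTY returns the earliest
    *booked* donor if any booked donor is waiting, else the earliest
    unbooked one. Ties break on donor id.
    """
    if not queue:
        raise ValueError("select_next called on an empty queue")
    if policy == "PRTY":
        booked = [q for q in queue if q[1] == "booked"]
        pool = booked if booked else list(queue)
    elif policy == "FIFO":
        pool = list(queue)
    else:
        raise ValueError(f"unknown queue policy {policy!r}")
    return min(pool, key=lambda q: (q[2], q[0]))[0]


# ---------------------------------------------------------------------------
# Engine internals
# ---------------------------------------------------------------------------

#: Per-donor pre-drawn randomness consumed by the run.
@dataclass
class _Draws:
    registration: float
    haemoglobin: float
    consultation: float
    pre_setup: float
    phlebotomy: float
    post_setup: float
    resting: float
    refreshment: float
    defer_hb: bool
    defer_cons: bool


def _predraw(
    arrivals: Sequence[ArrivalEvent],
    catalog: ProcessTimeCatalog,
    rates: DeferralRates,
    streams: StreamFamily,
) -> Dict[str, _Draws]:
    draws = {}
    for a in arrivals:
        reg_key = (
            "registration_booked" if a.donor_type == "booked" else "registration_unbooked"
        )
        p_cons = (
            rates.p_consultation_booked
            if a.donor_type == "booked"
            else rates.p_consultation_unbooked
        )
        draws[a.donor_id] = _Draws(
            registration=sample(catalog[reg_key], streams.stream(a.donor_id, reg_key)),
            haemoglobin=sample(
                catalog["haemoglobin"], streams.stream(a.donor_id, "haemoglobin")
            ),
            consultation=sample(
                catalog["consultation"], streams.stream(a.donor_id, "consultation")
            ),
            pre_setup=sample(catalog["pre_setup"], streams.stream(a.donor_id, "pre_setup")),
            phlebotomy=sample(
                catalog["phlebotomy"], streams.stream(a.donor_id, "phlebotomy")
            ),
            post_setup=sample(
                catalog["post_setup"], streams.stream(a.donor_id, "post_setup")
            ),
            resting=sample(catalog["resting"], streams.stream(a.donor_id, "resting")),
            refreshment=sample(
                catalog["refreshment"], streams.stream(a.donor_id, "refreshment")
            ),
            defer_hb=bernoulli(rates.p_haemoglobin, streams.stream(a.donor_id, "defer_hb")),
            defer_cons=bernoulli(p_cons, streams.stream(a.donor_id, "defer_cons")),
        )
    return draws


class _Pool:
    """Fixed pool of identical units; lowest free unit id is seized first."""

    def __init__(self, n: int):
        self.free = list(range(n))
        self.n = n

    def seize(self) -> int:
        self.free.sort()
        return self.free.pop(0)

    def release(self, unit: int) -> None:
        self.free.append(unit)

    @property
    def any_free(self) -> bool:
        return bool(self.free)


def run_day(
    layout: LayoutConfig,
    arrivals: Sequence[ArrivalEvent],
    catalog: ProcessTimeCatalog,
    rates: DeferralRates,
    streams: StreamFamily,
    day: DaySchedule,
    draws: Optional[Dict[str, _Draws]] = None,
) -> EventLog:
    """Simulate one day under ``layout`` and return the full event log.

    ``arrivals`` must be sorted by arrival time. The run is deterministic
    given ``streams`` (all randomness is pre-drawn per donor, keyed by
    donor and activity, independent of the layout). A pre-computed
    ``draws`` dict (from :func:`_predraw`) may be passed to share the
    identical randomness across the layouts of one CRN replication
    without re-deriving it.
    """
    if draws is None:
        draws = _predraw(arrivals, catalog, rates, streams)
    timetable = PhysicianTimetable(layout.physician_timetable, day)
    log = EventLog(layout=layout, day=day)

    clerks = _Pool(layout.n_clerks)
    nurses = _Pool(layout.n_nurses)
    beds = _Pool(layout.n_beds)
    hb_nurse = _Pool(1) if layout.has_hb_station else None
    phys_busy: set = set()  # physician unit ids in service

    reg_queue: List[Tuple[float, str]] = []  # (enqueue_time, donor)
    hb_queue: List[Tuple[float, str]] = []
    cons_queue: List[Tuple[float, str]] = []
    donation_queue: List[Tuple[float, str]] = []  # waiting for bed AND nurse
    post_queue: List[Tuple[float, str]] = []  # on bed, waiting for a nurse

    heap: List[tuple] = []
    seq = itertools.count()

    def push(t: float, kind: str, donor: Optional[str] = None, payload=None) -> None:
        heapq.heappush(heap, (t, next(seq), kind, donor, payload))

    def phys_units_on_duty(t: float) -> List[int]:
        if t < timetable.opening:
            return []
        units = [0, 1, 2]
        if timetable.fourth_on(t):
            units.append(3)
        return units

    def dispatch(t: float) -> None:
        # Post-setup first: it frees beds, and disconnecting a finished
        # donor takes precedence over starting a new setup.
        while post_queue and nurses.any_free:
            q_t, donor = post_queue.pop(0)
            unit = nurses.seize()
            rec = log.records[donor]
            rec.post_start = t
            rec.waits["post_setup"] = t - q_t
            d = draws[donor].post_setup
            rec.services["post_setup"] = d
            log.busy.append(BusyInterval("nurse", unit, t, t + d, "post_setup", donor))
            push(t + d, "post_end", donor, unit)
        while reg_queue and clerks.any_free:
            q_t, donor = reg_queue.pop(0)
            unit = clerks.seize()
            rec = log.records[donor]
            rec.reg_start = t
            rec.waits["registration"] = t - q_t
            d = draws[donor].registration
            rec.services["registration"] = d
            log.busy.append(BusyInterval("clerk", unit, t, t + d, "registration", donor))
            push(t + d, "reg_end", donor, unit)
        if hb_nurse is not None:
            while hb_queue and hb_nurse.any_free:
                q_t, donor = hb_queue.pop(0)
                unit = hb_nurse.seize()
                rec = log.records[donor]
                rec.hb_start = t
                rec.waits["haemoglobin"] = t - q_t
                d = draws[donor].haemoglobin
                rec.services["haemoglobin"] = d
                log.busy.append(
                    BusyInterval("hb_nurse", unit, t, t + d, "haemoglobin", donor)
                )
                push(t + d, "hb_end", donor, unit)
        while cons_queue:
            free_units = [u for u in phys_units_on_duty(t) if u not in phys_busy]
            if not free_units:
                break
            donor = select_next(
                [(d, log.records[d].donor_type, q_t) for q_t, d in cons_queue],
                layout.queue_policy,
                t,
            )
            q_t = next(q for q, d in cons_queue if d == donor)
            cons_queue.remove((q_t, donor))
            unit = min(free_units)
            phys_busy.add(unit)
            rec = log.records[donor]
            rec.cons_start = t
            rec.waits["consultation"] = t - q_t
            d = draws[donor].consultation
            if layout.hb_placement == "W":
                d += draws[donor].haemoglobin
            rec.services["consultation"] = d
            log.busy.append(BusyInterval("physician", unit, t, t + d, "consultation", donor))
            push(t + d, "cons_end", donor, unit)
        while donation_queue and beds.any_free and nurses.any_free:
            q_t, donor = donation_queue.pop(0)
            bed = beds.seize()
            nurse = nurses.seize()
            rec = log.records[donor]
            rec.bed_assigned = t
            rec.waits["donation_entry"] = t - q_t
            d = draws[donor].pre_setup
            rec.services["pre_setup"] = d
            log.busy.append(BusyInterval("nurse", nurse, t, t + d, "pre_setup", donor))
            push(t + d, "pre_end", donor, (nurse, bed))

    def defer(rec: DonorRecord, outcome: str, t: float) -> None:
        rec.outcome = outcome
        rec.exit = t

    # Seed the calendar: arrivals and staffing change points.
    for a in arrivals:
        log.records[a.donor_id] = DonorRecord(
            donor_id=a.donor_id, donor_type=a.donor_type, arrival=a.arrival, period=a.period
        )
        push(a.arrival, "arrival", a.donor_id)
    for t in timetable.change_points():
        push(t, "wake")

    bed_seized_at: Dict[str, Tuple[int, float]] = {}  # donor -> (bed unit, seize time)

    while heap:
        t, _, kind, donor, payload = heapq.heappop(heap)
        if kind == "arrival":
            reg_queue.append((t, donor))
        elif kind == "reg_end":
            clerks.release(payload)
            rec = log.records[donor]
            rec.reg_end = t
            if layout.hb_placement == "B":
                hb_queue.append((t, donor))
            else:
                cons_queue.append((t, donor))
        elif kind == "hb_end":
            hb_nurse.release(payload)
            rec = log.records[donor]
            rec.hb_end = t
            if draws[donor].defer_hb:
                defer(rec, "deferred_hb", t)
            elif layout.hb_placement == "B":
                cons_queue.append((t, donor))
            else:  # A: haemoglobin follows an accepted consultation
                donation_queue.append((t, donor))
        elif kind == "cons_end":
            phys_busy.discard(payload)
            rec = log.records[donor]
            rec.cons_end = t
            if layout.hb_placement == "W" and draws[donor].defer_hb:
                defer(rec, "deferred_hb", t)
            elif draws[donor].defer_cons:
                defer(rec, "deferred_consultation", t)
            elif layout.hb_placement == "A":
                hb_queue.append((t, donor))
            else:
                donation_queue.append((t, donor))
        elif kind == "pre_end":
            nurse, bed = payload
            nurses.release(nurse)
            bed_seized_at[donor] = (bed, log.records[donor].bed_assigned)
            rec = log.records[donor]
            rec.phleb_start = t
            d = draws[donor].phlebotomy
            rec.services["phlebotomy"] = d
            push(t + d, "phleb_end", donor)
        elif kind == "phleb_end":
            rec = log.records[donor]
            rec.phleb_end = t
            post_queue.append((t, donor))
        elif kind == "post_end":
            nurses.release(payload)
            rec = log.records[donor]
            rec.post_end = t
            d = draws[donor].resting
            rec.services["resting"] = d
            push(t + d, "rest_end", donor)
        elif kind == "rest_end":
            rec = log.records[donor]
            rec.rest_end = t
            bed, seized = bed_seized_at.pop(donor)
            log.busy.append(BusyInterval("bed", bed, seized, t, "donation", donor))
            beds.release(bed)
            d = draws[donor].refreshment
            rec.services["refreshment"] = d
            push(t + d, "exit", donor)
        elif kind == "exit":
            rec = log.records[donor]
            rec.exit = t
            rec.outcome = "completed"
        elif kind == "wake":
            pass
        dispatch(t)

    return log
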