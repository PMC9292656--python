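"""Independent brute-force day simulator used as a test oracle.

Deliberately structured unlike the engine: no event heap, no unit pools.
Donors are plain dicts with a stage label; resource occupancy is
re-derived at every step by counting donors in in-service stages; the
loop alternates between applying every enabled start at the current time
and advancing to the earliest pending completion. Only deterministic
(degenerate) service times are supported — enough to cross-check the
engine's event ordering and resource accounting on small scenarios.
"""

from dataclasses import dataclass
from typing import Dict, List, Optional


@dataclass
class OracleDonor:
    donor_id: str
    donor_type: str
    arrival: float
    times: Dict[str, float]  # durations: registration, haemoglobin, consultation,
    #                          pre_setup, phlebotomy, post_setup, resting, refreshment
    defer_hb: bool = False
    defer_cons: bool = False
    stage: str = "travelling"
    done_at: Optional[float] = None
    stamps: Dict[str, float] = None

    def __post_init__(self):
        self.stamps = {}


def _fourth_on(config: int, t: float, periods) -> bool:
    for s, e in periods:
        if s <= t < e:
            return t < s + 90.0 if config == 1 else t >= s + 30.0
    if t >= periods[-1][1]:
        return config == 2
    return False


def brute_force_day(layout, donors: List[OracleDonor], day) -> Dict[str, Dict[str, float]]:
    """Simulate by exhaustive scanning; returns per-donor timestamp dicts."""
    periods = [(p.start, p.end) for p in day.periods]
    in_service = {
        "registering": "clerk", "hb_testing": "hb", "consulting": "physician",
        "pre_setup": "nurse", "post_setup": "nurse",
    }

    def busy(resource: str) -> int:
        return sum(1 for d in donors if in_service.get(d.stage) == resource)

    def beds_busy() -> int:
        return sum(
            1 for d in donors
            if d.stage in ("pre_setup", "phlebotomy", "await_post", "post_setup", "resting")
        )

    def on_duty(t: float) -> int:
        if t < periods[0][0]:
            return 0
        return 3 + (1 if _fourth_on(layout.physician_timetable, t, periods) else 0)

    def queue(stage: str) -> List[OracleDonor]:
        q = [d for d in donors if d.stage == stage]
        return sorted(q, key=lambda d: (d.stamps[f"enter_{stage}"], d.donor_id))

    def start(d: OracleDonor, stage: str, t: float, duration_key: str) -> None:
        d.stage = stage
        d.stamps[f"{stage}_start"] = t
        d.done_at = t + d.times[duration_key]

    def apply_starts(t: float) -> bool:
        changed = False
        # post-setup outranks new donation entries for nurses
        for d in queue("await_post"):
            if busy("nurse") < layout.n_nurses:
                start(d, "post_setup", t, "post_setup")
                changed = True
        for d in queue("await_reg"):
            if busy("clerk") < layout.n_clerks:
                start(d, "registering", t, "registration")
                changed = True
        if layout.hb_placement in ("A", "B"):
            for d in queue("await_hb"):
                if busy("hb") < 1:
                    start(d, "hb_testing", t, "haemoglobin")
                    changed = True
        cons_q = queue("await_cons")
        while cons_q and busy("physician") < on_duty(t):
            if layout.queue_policy == "PRTY":
                booked = [d for d in cons_q if d.donor_type == "booked"]
                pick = booked[0] if booked else cons_q[0]
            else:
                pick = cons_q[0]
            dur = d_cons_duration(pick)
            pick.stage = "consulting"
            pick.stamps["consulting_start"] = t
            pick.done_at = t + dur
            cons_q.remove(pick)
            changed = True
        for d in queue("await_bed"):
            if beds_busy() < layout.n_beds and busy("nurse") < layout.n_nurses:
                start(d, "pre_setup", t, "pre_setup")
                changed = True
        return changed

    def d_cons_duration(d: OracleDonor) -> float:
        dur = d.times["consultation"]
        if layout.hb_placement == "W":
            dur += d.times["haemoglobin"]
        return dur

    def enter(d: OracleDonor, stage: str, t: float) -> None:
        d.stage = stage
        d.stamps[f"enter_{stage}"] = t

    def complete(d: OracleDonor, t: float) -> None:
        s = d.stage
        d.done_at = None
        d.stamps[f"{s}_end"] = t
        if s == "registering":
            enter(d, "await_hb" if layout.hb_placement == "B" else "await_cons", t)
        elif s == "hb_testing":
            if d.defer_hb:
                d.stage = "out_deferred_hb"
                d.stamps["exit"] = t
            elif layout.hb_placement == "B":
                enter(d, "await_cons", t)
            else:
                enter(d, "await_bed", t)
        elif s == "consulting":
            if layout.hb_placement == "W" and d.defer_hb:
                d.stage = "out_deferred_hb"
                d.stamps["exit"] = t
            elif d.defer_cons:
                d.stage = "out_deferred_consultation"
                d.stamps["exit"] = t
            elif layout.hb_placement == "A":
                enter(d, "await_hb", t)
            else:
                enter(d, "await_bed", t)
        elif s == "pre_setup":
            d.stage = "phlebotomy"
            d.stamps["phlebotomy_start"] = t
            d.done_at = t + d.times["phlebotomy"]
        elif s == "phlebotomy":
            enter(d, "await_post", t)
        elif s == "post_setup":
            d.stage = "resting"
            d.done_at = t + d.times["resting"]
        elif s == "resting":
            d.stamps["resting_end"] = t
            d.stage = "refreshing"
            d.done_at = t + d.times["refreshment"]
        elif s == "refreshing":
            d.stage = "out_completed"
            d.stamps["exit"] = t

    # Wake times where physician staffing can step up.
    staffing_steps = sorted(
        {s for s, e in periods} | {s + 30.0 for s, e in periods}
        | {s + 90.0 for s, e in periods} | {e for s, e in periods}
    )

    t = min(d.arrival for d in donors) if donors else 0.0
    arrived = set()
    while True:
        for d in donors:
            if d.donor_id not in arrived and d.arrival <= t:
                arrived.add(d.donor_id)
                enter(d, "await_reg", d.arrival)
        while apply_starts(t):
            pass
        pending = [d.done_at for d in donors if d.done_at is not None]
        upcoming_arrivals = [d.arrival for d in donors if d.donor_id not in arrived]
        upcoming_steps = [s for s in staffing_steps if s > t]
        candidates = pending + upcoming_arrivals + upcoming_steps
        if not pending and not upcoming_arrivals:
            break
        t_next = min(candidates)
        for d in donors:
            if d.done_at is not None and d.done_at == t_next:
                complete(d, t_next)
        t = t_next

    out = {}
    for d in donors:
        stamps = dict(d.stamps)
        stamps["arrival"] = d.arrival
        stamps["outcome"] = d.stage.replace("out_", "")
        out[d.donor_id] = stamps
    return out
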