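"""Engine behaviour: hand traces, queue disciplines, staffing, invariants."""

import itertools

import pytest

from donorflow import (
    BehaviourParams,
    DeferralRates,
    LayoutConfig,
    PhysicianTimetable,
    compute_kpis,
    default_catalog,
    realize_arrivals,
    run_day,
    select_next,
)
from donorflow.schedule import ArrivalEvent, baseline_day, generate_synthetic_day
from donorflow.streams import StreamFamily

from oracle import OracleDonor, brute_force_day

APPROX = dict(abs=1e-9)

DEGENERATE_TIMES = {
    "registration": 1.77,
    "haemoglobin": 1.67,
    "consultation": 18.33,
    "pre_setup": 1.6,
    "phlebotomy": 13.26,
    "post_setup": 1.5,
    "resting": 5.0,
    "refreshment": 14.22,
}


def empty_day():
    return generate_synthetic_day(seed=0, counts=[(0, 0, 0)] * 3)


def arrivals_at(times_types):
    """[(clock, type), ...] -> sorted ArrivalEvents with stable ids."""
    evs = [
        ArrivalEvent(f"d1-{'b' if typ == 'booked' else 'u'}{i:02d}", typ, t, 1)
        for i, (t, typ) in enumerate(times_types)
    ]
    return sorted(evs, key=lambda e: (e.arrival, e.donor_id))


class TestHandTraces:
    def test_single_booked_donor_layout_w(self, degenerate_catalog, no_deferrals):
        """Uncongested path: cycle time is the exact sum of service times."""
        day = empty_day()
        arr = arrivals_at([(450.0, "booked")])
        log = run_day(LayoutConfig(), arr, degenerate_catalog, no_deferrals,
                      StreamFamily(0), day)
        rec = log.donors[0]
        assert rec.outcome == "completed"
        assert rec.reg_end == pytest.approx(451.77, **APPROX)
        # W: consultation occupies the physician for consultation + hb time
        assert rec.cons_start == pytest.approx(451.77, **APPROX)
        assert rec.cons_end == pytest.approx(451.77 + 20.0, **APPROX)
        assert rec.phleb_end == pytest.approx(471.77 + 1.6 + 13.26, **APPROX)
        assert rec.exit == pytest.approx(450.0 + 57.35, **APPROX)
        assert rec.cycle_time == pytest.approx(57.35, **APPROX)
        assert rec.queue_time == pytest.approx(0.0, **APPROX)

    @pytest.mark.parametrize("placement", ["A", "B"])
    def test_single_donor_separate_station_same_total(
        self, degenerate_catalog, no_deferrals, placement
    ):
        day = empty_day()
        arr = arrivals_at([(450.0, "booked")])
        log = run_day(LayoutConfig(hb_placement=placement), arr, degenerate_catalog,
                      no_deferrals, StreamFamily(0), day)
        rec = log.donors[0]
        # hb is a separate 1.67-min stage; consultation shrinks to 18.33,
        # so the uncongested total is unchanged
        assert rec.cons_end - rec.cons_start == pytest.approx(18.33, **APPROX)
        assert rec.hb_end - rec.hb_start == pytest.approx(1.67, **APPROX)
        assert rec.cycle_time == pytest.approx(57.35, **APPROX)

    def test_nurse_contention_serializes_presetup_not_phlebotomy(
        self, degenerate_catalog, no_deferrals
    ):
        """3 donors, 2 nurses: third pre-setup waits for a nurse, but all
        three phlebotomies overlap once started."""
        cat = degenerate_catalog.replace(
            pre_setup=degenerate_catalog["pre_setup"].degenerate(5.0)
        )
        day = empty_day()
        arr = arrivals_at([(450.0, "booked"), (450.1, "booked"), (450.2, "booked")])
        layout = LayoutConfig(n_clerks=2, n_nurses=2, n_beds=5)
        log = run_day(layout, arr, cat, no_deferrals, StreamFamily(0), day)
        recs = sorted(log.donors, key=lambda r: r.arrival)
        d1, d2, d3 = recs
        # regs: d1,d2 in parallel (2 clerks), d3 waits for a clerk
        assert d3.reg_start == pytest.approx(451.77, **APPROX)
        # consultations overlap (4 physicians on duty)
        assert d3.cons_end == pytest.approx(453.54 + 20.0, **APPROX)
        # donation room: d1, d2 grab both nurses at 471.77/471.87;
        # d3 is ready at 473.54 but the first nurse frees at 476.77
        assert d1.bed_assigned == pytest.approx(471.77, **APPROX)
        assert d3.bed_assigned == pytest.approx(476.77, **APPROX)
        assert d3.waits["donation_entry"] == pytest.approx(476.77 - 473.54, **APPROX)
        # all three phlebotomies overlap
        latest_start = max(r.phleb_start for r in recs)
        earliest_end = min(r.phleb_end for r in recs)
        assert latest_start < earliest_end

    def test_hb_deferral_before_consultation_frees_physicians(
        self, degenerate_catalog
    ):
        day = empty_day()
        arr = arrivals_at([(450.0, "booked"), (455.0, "unbooked")])
        rates = DeferralRates(0.0, 0.0, 1.0)  # everyone anaemic
        log = run_day(LayoutConfig(hb_placement="B"), arr, degenerate_catalog,
                      rates, StreamFamily(0), day)
        assert all(r.outcome == "deferred_hb" for r in log.donors)
        assert all(r.cons_start is None for r in log.donors)
        assert not any(b.resource == "physician" for b in log.busy)

    def test_empty_day_empty_log(self, catalog, no_deferrals):
        log = run_day(LayoutConfig(), [], catalog, no_deferrals,
                      StreamFamily(0), empty_day())
        assert log.donors == [] and log.busy == []
        assert all(u == 0.0 for u in compute_kpis(log).utilizations.values())


class TestSelectNext:
    QUEUE = [("u1", "unbooked", 10.0), ("b1", "booked", 12.0)]

    def test_fifo_takes_earliest(self):
        assert select_next(self.QUEUE, "FIFO") == "u1"

    def test_priority_takes_booked_first(self):
        assert select_next(self.QUEUE, "PRTY") == "b1"

    def test_priority_falls_back_to_earliest_unbooked(self):
        q = [("u2", "unbooked", 8.0), ("u1", "unbooked", 5.0)]
        assert select_next(q, "PRTY") == "u1"

    def test_tie_breaks_on_donor_id(self):
        q = [("b2", "booked", 5.0), ("b1", "booked", 5.0)]
        assert select_next(q, "FIFO") == "b1"

    def test_empty_queue_is_contract_violation(self):
        with pytest.raises(ValueError):
            select_next([], "FIFO")


@pytest.fixture(scope="module")
def day():
    return empty_day()


class TestPhysicianTimetable:
    def test_config1_fourth_at_period_start(self, day):
        tt = PhysicianTimetable(1, day)
        assert tt.on_duty(460.0) == 4
        assert tt.on_duty(450.0 + 95.0) == 3

    def test_config2_fourth_at_period_end(self, day):
        tt = PhysicianTimetable(2, day)
        assert tt.on_duty(460.0) == 3
        assert tt.on_duty(450.0 + 95.0) == 4

    @pytest.mark.parametrize("config", [1, 2])
    def test_period_integral_is_450_minutes(self, day, config):
        tt = PhysicianTimetable(config, day)
        for start, end in [(450, 570), (570, 690), (690, 810)]:
            # integrate the step function between its change points
            pts = sorted({start, start + 30, start + 90, end})
            total = sum(
                tt.on_duty((a + b) / 2) * (b - a) for a, b in zip(pts, pts[1:])
            )
            assert total == pytest.approx(450.0)

    def test_before_opening_nobody_on_duty(self, day):
        assert PhysicianTimetable(1, day).on_duty(400.0) == 0

    def test_overtime_keeps_closing_staffing(self, day):
        assert PhysicianTimetable(1, day).on_duty(850.0) == 3
        assert PhysicianTimetable(2, day).on_duty(850.0) == 4


def _degenerate_oracle_donors(arrivals, defer_hb=(), defer_cons=()):
    donors = []
    for a in arrivals:
        times = dict(DEGENERATE_TIMES)
        times["registration"] = 1.77 if a.donor_type == "booked" else 2.4
        donors.append(
            OracleDonor(
                donor_id=a.donor_id, donor_type=a.donor_type, arrival=a.arrival,
                times=times,
                defer_hb=a.donor_id in defer_hb, defer_cons=a.donor_id in defer_cons,
            )
        )
    return donors


class TestOracleEquivalence:
    """Engine log vs the brute-force simulator, exact, on <=5 donors."""

    SCENARIOS = list(itertools.product(["FIFO", "PRTY"], [1, 2], ["W", "A", "B"]))

    @pytest.mark.parametrize("policy,timetable,placement", SCENARIOS)
    def test_five_donor_degenerate_day(
        self, degenerate_catalog, no_deferrals, policy, timetable, placement
    ):
        day = empty_day()
        arr = arrivals_at(
            [(450.0, "booked"), (452.0, "unbooked"), (452.0, "booked"),
             (460.0, "booked"), (465.0, "unbooked")]
        )
        layout = LayoutConfig(policy, timetable, placement, 2, 1, 5)
        log = run_day(layout, arr, degenerate_catalog, no_deferrals,
                      StreamFamily(0), day)
        expected = brute_force_day(layout, _degenerate_oracle_donors(arr), day)
        for rec in log.donors:
            exp = expected[rec.donor_id]
            assert rec.outcome == exp["outcome"]
            assert rec.reg_start == pytest.approx(exp["registering_start"], **APPROX)
            assert rec.reg_end == pytest.approx(exp["registering_end"], **APPROX)
            assert rec.cons_start == pytest.approx(exp["consulting_start"], **APPROX)
            assert rec.cons_end == pytest.approx(exp["consulting_end"], **APPROX)
            if placement in ("A", "B"):
                assert rec.hb_start == pytest.approx(exp["hb_testing_start"], **APPROX)
                assert rec.hb_end == pytest.approx(exp["hb_testing_end"], **APPROX)
            assert rec.bed_assigned == pytest.approx(exp["pre_setup_start"], **APPROX)
            assert rec.phleb_start == pytest.approx(exp["phlebotomy_start"], **APPROX)
            assert rec.phleb_end == pytest.approx(exp["phlebotomy_end"], **APPROX)
            assert rec.post_start == pytest.approx(exp["post_setup_start"], **APPROX)
            assert rec.post_end == pytest.approx(exp["post_setup_end"], **APPROX)
            assert rec.exit == pytest.approx(exp["exit"], **APPROX)

    @pytest.mark.parametrize("placement", ["W", "A", "B"])
    def test_deferrals_match_oracle(self, degenerate_catalog, placement):
        day = empty_day()
        arr = arrivals_at([(450.0, "booked"), (451.0, "unbooked"), (453.0, "booked")])
        layout = LayoutConfig("FIFO", 1, placement, 2, 1, 5)
        # force donor 0 to an hb deferral and donor 1 to a consultation
        # deferral via degenerate per-type rates
        rates = DeferralRates(0.0, 1.0, 0.0)
        import donorflow.engine as eng

        draws = eng._predraw(arr, degenerate_catalog, rates, StreamFamily(0))
        draws[arr[0].donor_id].defer_hb = True
        log = run_day(layout, arr, degenerate_catalog, rates, StreamFamily(0), day,
                      draws=draws)
        defer_hb = {arr[0].donor_id}
        defer_cons = {a.donor_id for a in arr if a.donor_type == "unbooked"}
        expected = brute_force_day(
            layout, _degenerate_oracle_donors(arr, defer_hb, defer_cons), day
        )
        for rec in log.donors:
            assert rec.outcome == expected[rec.donor_id]["outcome"]
            assert rec.exit == pytest.approx(expected[rec.donor_id].get("exit"), **APPROX)


def _stochastic_log(seed=3, layout=LayoutConfig(), load=1.0):
    day = generate_synthetic_day(seed=seed, load_factor=load)
    streams = StreamFamily(seed)
    arr = realize_arrivals(day, BehaviourParams(), streams)
    return run_day(layout, arr, default_catalog(), DeferralRates(), streams, day), day


class TestInvariants:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_flow_conservation(self, seed):
        log, _ = _stochastic_log(seed=seed)
        outcomes = [r.outcome for r in log.donors]
        assert None not in outcomes
        assert len(outcomes) == (
            outcomes.count("completed")
            + outcomes.count("deferred_hb")
            + outcomes.count("deferred_consultation")
        )

    @pytest.mark.parametrize("placement", ["W", "A", "B"])
    def test_timestamp_monotonicity(self, placement):
        log, _ = _stochastic_log(layout=LayoutConfig(hb_placement=placement))
        for rec in log.donors:
            ts = rec.timestamps()
            assert all(a <= b + 1e-9 for a, b in zip(ts, ts[1:]))

    def test_cycle_time_identity(self):
        """cycle = total service + total queueing, exactly, per donor."""
        log, _ = _stochastic_log()
        for rec in log.completed():
            assert rec.cycle_time == pytest.approx(
                rec.service_time + rec.queue_time, abs=1e-9
            )

    @pytest.mark.parametrize("placement", ["W", "B"])
    def test_capacity_never_exceeded(self, placement):
        layout = LayoutConfig(hb_placement=placement)
        log, day = _stochastic_log(layout=layout, load=1.2)
        tt = PhysicianTimetable(layout.physician_timetable, day)
        limits = {"clerk": layout.n_clerks, "nurse": layout.n_nurses,
                  "bed": layout.n_beds, "hb_nurse": 1}
        by_kind = {}
        for b in log.busy:
            by_kind.setdefault(b.resource, []).append(b)
        for kind, intervals in by_kind.items():
            for probe in intervals:
                t = probe.start
                concurrent = sum(
                    1 for b in intervals if b.start <= t < b.end
                )
                if kind == "physician":
                    # a consultation can only START on an on-duty unit;
                    # a unit that went off shift may still be finishing
                    # (overtime), so concurrency is capped by the head
                    # count of 4, not by the instantaneous on-duty level
                    assert concurrent <= 4
                    assert tt.on_duty(t) >= 1
                    if probe.unit == 3:
                        assert tt.fourth_on(t)
                else:
                    assert concurrent <= limits[kind]
        # busy intervals of any single unit never overlap
        for kind, intervals in by_kind.items():
            units = {}
            for b in intervals:
                units.setdefault(b.unit, []).append((b.start, b.end))
            for spans in units.values():
                spans.sort()
                assert all(a_end <= b_start + 1e-9
                           for (_, a_end), (b_start, _) in zip(spans, spans[1:]))

    def test_unlimited_resources_no_queueing(self, degenerate_catalog, no_deferrals):
        day = empty_day()
        arr = arrivals_at([(450.0 + i, "booked") for i in range(5)])
        layout = LayoutConfig("FIFO", 1, "W", 99, 99, 99)
        log = run_day(layout, arr, degenerate_catalog, no_deferrals,
                      StreamFamily(0), day)
        # only the physician pool (4 heads) remains finite; 5 spaced
        # arrivals with 20-min consultations still queue there, so probe
        # with 3 donors instead
        arr = arrivals_at([(450.0, "booked"), (450.0, "booked"), (450.0, "booked")])
        log = run_day(layout, arr, degenerate_catalog, no_deferrals,
                      StreamFamily(0), day)
        for rec in log.donors:
            assert rec.queue_time == pytest.approx(0.0, **APPROX)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_more_beds_never_increase_bed_waits_under_crn(self, seed):
        # Nurses are made abundant so donation-room entry waits on beds
        # alone; under CRN (identical arrivals and draws) adding a bed
        # then cannot delay anyone's entry.
        day = generate_synthetic_day(seed=seed, load_factor=1.2)
        streams = StreamFamily(seed)
        arr = realize_arrivals(day, BehaviourParams(), streams)
        cat, rates = default_catalog(), DeferralRates()
        few = run_day(LayoutConfig(n_nurses=99, n_beds=3), arr, cat, rates,
                      streams, day)
        many = run_day(LayoutConfig(n_nurses=99, n_beds=4), arr, cat, rates,
                       streams, day)
        contended = 0
        for donor_id, rec3 in few.records.items():
            w3 = rec3.waits.get("donation_entry")
            w4 = many.records[donor_id].waits.get("donation_entry")
            if w3 is not None and w4 is not None:
                assert w4 <= w3 + 1e-9
                contended += w3 > 1e-9
        assert contended > 0  # the scenario actually exercises bed waits

    def test_crn_bit_reproducibility(self):
        a, _ = _stochastic_log(seed=9)
        b, _ = _stochastic_log(seed=9)
        assert a.to_frame().equals(b.to_frame())
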