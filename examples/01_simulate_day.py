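"""Simulate one day at the collection centre and read off its KPIs.

Builds a calibrated synthetic day plan (three two-hour periods, donor
volumes at the reference centre's observed loading), realizes stochastic
arrivals (slot filling, no-shows, walk-ins), runs the baseline layout
FIFO-1-W-01 and prints the donor- and resource-facing indicators.
"""

from donorflow import (
    BehaviourParams,
    DeferralRates,
    LayoutConfig,
    StreamFamily,
    compute_kpis,
    default_catalog,
    realize_arrivals,
    run_day,
)
from donorflow.schedule import baseline_day

day = baseline_day(seed=1)
streams = StreamFamily(master_seed=1, replication=0)
arrivals = realize_arrivals(day, BehaviourParams(), streams)
log = run_day(LayoutConfig(), arrivals, default_catalog(), DeferralRates(),
              streams, day)
report = compute_kpis(log)

print(f"layout {report.layout_name}: {report.n_arrivals} arrivals, "
      f"{report.n_completed} completed donations, "
      f"{report.n_deferred_hb + report.n_deferred_consultation} deferrals")
ct = report.times["cycle_time"]
qt = report.times["queue_time"]
print(f"cycle time  min/avg/max = {ct.min:5.1f} / {ct.avg:5.1f} / {ct.max:5.1f} min")
print(f"queue time  min/avg/max = {qt.min:5.1f} / {qt.avg:5.1f} / {qt.max:5.1f} min")
for res, u in report.utilizations.items():
    print(f"utilization {res:<10} = {u:.2f}")
for k, vals in report.periods.items():
    h, m = divmod(vals["last_exit"], 60)
    print(f"period {k}: used physician capacity {vals['used_capacity']:5.1f} min, "
          f"last consultation exit {int(h):02d}:{int(m):02d}")
print("Cycle time counts everything from the front door to leaving the "
      "canteen; physicians near 0.7 utilization is the expected baseline.")
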