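# Methods

## Model

The simulator describes one working day of a fixed-site whole-blood
collection centre as a network of queues served by four resource kinds:
clerks (registration), physicians (consultation), nurses (phlebotomy
pre/post-setup; plus one dedicated nurse when haemoglobin testing has
its own station) and beds. The canteen is uncapacitated. State changes
only at event instants (arrivals, service completions, physician shift
steps); there is no fixed tick. A donor's path is

registration → [haemoglobin station, placement B] → consultation →
[haemoglobin station, placement A] → bed + nurse pre-setup →
phlebotomy (nurse released) → nurse post-setup → rest on bed →
canteen → exit,

with Bernoulli deferral gates at the haemoglobin test (p = 5e-3, both
donor types) and the consultation (booked 5.03e-3, walk-in 4.523e-2 —
walk-ins are deferred at least five times more often, being less
pre-screened). The combined acceptance rates are 99% and 95%. Deferral
outcomes are fixed per donor at the start of a run, which keeps them
identical across layouts under common random numbers.

Assumptions: whole-blood donations only; no reneging or balking (queues
are unbounded and waiting is the performance metric); no staff breaks;
registration and the haemoglobin-station queue are FIFO in every layout
(the priority policy applies only to the consultation queue, where
booked donors, if any are waiting, are always called first); under
placement B a donor deferred at the haemoglobin station leaves without
seeing a physician; under W the consultation occupies the physician for
the consultation draw plus the haemoglobin draw and either deferral gate
may trigger at its end.

## Time, staffing and the closing rule

Clock times are decimal minutes from midnight; the day is three
contiguous two-hour periods, 450–570, 570–690, 690–810 (7:30–13:30).
Physician capacity is 450 physician-minutes per period = 3.75
physicians: three cover the full period, a fourth covers 90 minutes at
the period start (timetable 1) or end (timetable 2). A consultation may
start only on a unit that is on duty at that instant; a unit whose
shift ends mid-consultation finishes it (overtime). After the last
period the closing staffing level continues serving the residual queue
until the floor drains — the alternative (no consultation starts after
closing) would strand queued donors and contradict measuring the last
donor's exit past closing, which is itself a KPI.

## Input plans and the synthetic generator

The simulator's input is the day plan of an upstream appointment
scheduler: per period, already-booked donors, pre-allocated slots,
expected walk-ins and a queue-penalty weight; day-level nominal capacity
ct = 450 min and standard consultation slot r = 20 min. The real
scheduler solutions for the reference centre are not available, so
`generate_synthetic_day` emulates them. In calibrated mode the expected
consultation workload per period, (n_booked + pfill·n_preallocated +
n_walkins)·r, equals `load_factor` × ct; the composition is drawn once
per seed (walk-ins ~15–25% of the flow, a 20–40% pre-allocated share).

The *study baseline day* uses `load_factor = 0.75`. The scheduler treats
the 450 minutes as a ceiling, not a target, and the reference centre's
observed operating point leaves physicians at roughly 70% saturation;
loading the synthetic day to 100% of nominal capacity would push
physician utilization above 0.9 and misrepresent the baseline. At 0.75
the baseline layout shows physician utilization ≈ 0.67 and mean cycle
times in the low 60s of minutes, consistent with a reported true mean
of 65 minutes.

Default weights are w = (2, 1.5, 1): the scheduler we emulate penalizes
queue accumulation most in the first period. The true weight values are
not published; this choice only needs to produce the documented
*direction* of the feedback (reversal shifts donors toward the morning)
with a magnitude that keeps the post-feedback first period just under
its nominal capacity.

What the generator does *not* emulate: blood-type balancing across days,
donor-specific appointment times (arrivals are uniform within periods),
time-varying no-show or deferral rates, and day-to-day correlation.
Passing tests therefore demonstrate correctness of the machinery and of
direction-level findings, not magnitude-level agreement with any real
centre's ledger.

## Service-time catalogue

Minutes; means in brackets. Registration: booked normal(1.77, 0.612),
walk-in lognormal with mean 2.4 and sd 0.82 of the distribution itself
(the log-scale parameters are derived internally; the stated values are
interpreted as the distribution's own moments since no log qualifier
accompanies them). Consultation: triangular(16.5, 20, mode 18.33)
[18.277]; haemoglobin: uniform(1.34, 2) [1.67] — together 19.95, i.e.
the 20-minute slot the scheduler plans with. Pre-setup:
normal(1.6, 0.284); phlebotomy: Weibull(scale 4.23, shape 1.82) shifted
by 9.5 [≈13.26]; post-setup: uniform(1, 2); rest: triangular(4, 10, 5);
refreshment: lognormal(14.22, 7.11). Normal draws ≤ 0 are resampled
rather than clamped: service times must be positive, and at these
parameters the truncation moves the mean by well under 0.01 min.

## Common random numbers

Every random stream is keyed by (master seed, replication, donor id,
activity) through hashed `SeedSequence` spawn keys. Because keys never
involve the layout, replication j consumes bit-identical arrival
realizations, service times and deferral outcomes in all 144 layouts,
even when a layout change reorders events — the property that makes
paired layout contrasts low-variance. Donor ids encode period, origin
(booked / pre-allocated / walk-in) and slot index so the keying survives
schedule edits that preserve slots.

## Statistics

*Validation.* Replicated baseline mean cycle times are tested against
the centre's reported 65 minutes with a two-sided one-sample t-test
(α = 0.05). Because failing to reject is weak evidence, the critical
difference δ = |x̄ − μ|/s is computed and the type-II error β(δ) and the
replication count for β ≤ 0.05 are obtained by numerically inverting the
noncentral-t power function rather than reading an operating-
characteristic chart; the chart-derived figure of 30 replications for a
worked example with δ = 0.890 need not coincide with the computed
requirement, and both are reported.

*ANOVA.* Per-KPI ordinary least squares with six categorical main
effects and all fifteen two-factor interactions; p-values from type-II
sums of squares (the design is balanced, so the convention is
immaterial; unbalanced input triggers a warning naming it). Three
significance tiers (0.001/0.01/0.05) mirror how such effect tables are
conventionally typeset. "Multivariate" screening is implemented as
univariate ANOVAs over multiple KPIs, which is what an effect-per-KPI
table reports; no MANOVA statistic is computed. Normality over
replications is checked with a q-q probability-plot correlation. No
multiple-comparison correction is applied.

*Cost-efficiency and rankings.* Throughput rate (1/mean cycle time) is
regressed on layout cost; isocost winners are the highest-rate layouts
at each cost level. Stakeholder selections use an explicit rule the
source analysis leaves informal: lexicographic on the stakeholder's
primary score — donors: mean cycle time (cost ignored); resources: mean
utilization of nurses/clerks/beds minus physician utilization;
management: throughput per CU — with ties within one standard error of
the best broken by lower cost, then name.

## Feedback surrogate

The true scheduler is an external optimization model and out of scope.
`rebalance_day` reproduces its re-run qualitatively: consultation slots
become 18.33 min when haemoglobin testing leaves the consultation (the
planning value for the consultation-only stage, used as conventionally
printed; the exact triangular mean is 18.277), weights are reversed, and
donors are reallocated proportionally to weight-scaled period capacities
(1/w_k normalized to mean one, times ct_k/r'), water-filling against
each period's physical cap of ct_k/r' consultations. Largest-remainder
rounding preserves the booked / pre-allocated / walk-in totals — and
hence the daily donor count — exactly. A pure greedy fill-to-cap was
rejected: with reversed weights it empties the last period entirely,
which is qualitatively wrong for a scheduler that merely re-weights
queue penalties. An adjustment that changes nothing returns the day
unchanged; days whose total workload exceeds aggregate capacity are
reported infeasible and returned unmodified. One feedback pass is the
validated mode; `apply_feedback(iterations=...)` exists as a hook for a
full optimization–simulation loop.

## Numerical choices and problem sizes

Event ties break on insertion order; queue ties on (enqueue time, donor
id). The per-donor identity cycle = Σ services + Σ waits holds to 1e-9
min and is asserted in tests. KPI strata with no donors are reported as
NaN, never zero. Utilization counts busy minutes within opening hours
over scheduled availability (physicians 1350 min/day; other resources
count × 360 min). Per-period capacity is attributed by the donor's
arrival period by default (the period the scheduler booked them into);
attribution by consultation-start period is available as an option.

The full factorial study (144 layouts × 30 CRN replications = 4320
runs) plus its analysis completes in a few seconds on one CPU; the
ANOVA null-calibration check uses 500 pure-noise syntheses at 2
replications per cell, a size chosen to keep the whole verification
suite interactive. Directional checks (priority-policy starvation of
walk-ins, feedback effects) use deliberately overloaded synthetic days
with paired replications, because the mechanisms they probe only bind
under congestion.

## Known limitations

Magnitudes depend on the synthetic day and are not comparable to any
specific centre's published figures; only design identities, calibrated
bands and effect directions are. Nurse/bed interaction means donation-
room entry waits on both resources jointly; "bed wait" is reported as
that joint wait. The part-time physician is modelled as one unit whose
consultations may overrun its shift; real centres may instead hand
patients over. Apheresis, mobile collection, staff breaks and
differentiated shifts are out of scope.
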