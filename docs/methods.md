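# Methods

`clinicflow` models the daily flow of a high-volume outpatient (retina)
clinic operating under pandemic-era distancing constraints. It has three
layers: a synthetic EMR event-log generator, a cycle-time analysis that
turns timestamp logs into simulation parameters, and a discrete-event
simulation (DES) of the clinic day with a volume × staffing experiment grid
on top.

## Cycle-time analysis

Each encounter carries a sparse set of named timestamps (check-in, in with
technician, done rooming, dilating in waiting room, waiting for imaging,
image completion, in with provider, visit complete, visit complete — note
pending, check-out). Derived intervals, all in minutes:

- **visit length** = visit end − earliest present stamp, where the visit end
  is the *earlier* of "visit complete" and "visit complete, note pending";
- **check-in-to-technician** = in-with-technician − check-in (the
  waiting-room-time proxy for the simulation);
- **time with technician** = (earliest post-rooming marker − check-in) −
  check-in-to-technician, where the markers are done-rooming,
  dilating-in-waiting-room and waiting-for-imaging. When no post-rooming
  marker exists the in-with-technician stamp itself is the fallback, making
  the interval 0; zeros are retained, since front-desk workflows really do
  produce simultaneous stamps.
- **check-in-to-provider**, **check-in-to-image-completion**: differences
  from check-in;
- **provider phase** = visit length − check-in-to-provider. Because the EMR
  frequently flags two rooms "in with provider" at once, the provider phase
  is halved per encounter before use as the simulation's examination time.

Intervals with a missing operand are missing; negative intervals are treated
as data-entry errors, set missing, and the record flagged erroneous.
Records with missing/erroneous stamps still count in volume reports.
Summaries use the sample SD (n−1); a single observation reports SD 0 with
`sd_defined=False`.

Era contrasts use Welch's t by default (group sizes and variances differ
widely between eras; a pooled-variance flag exists), Pearson chi-square
without continuity correction for proportions (Bonferroni applied at the
family level by the caller, since the number of simultaneous contrasts is a
reporting decision), and a pooled two-proportion z-test for top-box
(rating = 5 on the 1–5 Likert scale) satisfaction rates.

## Synthetic event logs

Real encounter-level EMR data are confidential, so the generator emulates
their structure. Timestamps are built cumulatively from independent phase
durations: check-in (uniform over the clinic day), a check-in-to-technician
wait, the technician work-up, optional dilation and imaging branches, and
the provider phase. Durations are lognormal, moment-matched to the
configured (mean, SD) and left-clipped at 0.5 min — clinic cycle times are
nonnegative and right-skewed with medians below means; gamma and truncated
normal are available as alternatives. Ages are truncated normal on the
configured range; procedure flags are independent Bernoulli draws;
timestamp missingness is completely at random over non-check-in stamps,
hitting exactly `round(rate·n)` records.

Era presets (pandemic-era in-person: check-in-to-tech 3±4, technician
19±14, provider phase 14±26 min, dilation in 19% and imaging in 24% of
encounters, ages 76.8±13.4 on [22, 102], 82% missingness; pre-pandemic:
14±15 wait, provider phase 18±28, dilation 87%, OCT 71%, ages 74.3±13.6,
21% missingness) reproduce the era-level cycle-time and procedure-mix
targets: mean visits of ≈47 and ≈87 minutes respectively. The dilation
(25±10) and imaging (15±8) branch means are chosen so the cumulative
check-in-to-provider means land near their era targets (33 and 69 min).

What the generator does *not* emulate: correlation between procedures and
durations, age–duration dependence, day-of-week effects, and
informative missingness. Tests passing on synthetic data therefore
demonstrate correctness of the derivation/estimation machinery and
distribution-level fidelity, not validity on any real clinic's data.

Known preset inconsistencies in the era-level targets themselves: the
pandemic-era dilation categories (3% one-eye, 6% both-eye) do not sum to
the 19% any-dilation rate used by the simulation — the preset keeps the
both-eye rate and assigns the remainder to one-eye; the pre-pandemic
"imaging in 83% of visits" exceeds what independent OCT (71%) and
other-imaging (4%) flags can produce, so the any-imaging rate is ≈72%.

## The clinic-day simulation

An event-calendar (heap) DES; no process framework is used. Entities and
resources:

- **Appointment grid**: 11 morning + 11 afternoon 15-minute slots
  (2 h 45 min sessions) separated by a 105-minute break; opening at 08:00.
  `n_providers × volume_per_provider` patients are assigned round-robin over
  the chronologically ordered slots (excess stacks evenly from the earliest
  slot) and round-robin to named providers.
- **Waiting area**: a distancing cap (default 10 people). Patients plus
  their guests (one guest per patient with probability 1/15) count toward
  the cap from admission until the patient is roomed; the guest then leaves.
  Arrivals that cannot fit hold in an outside FIFO queue.
- **Flow**: admitted patients spend a sampled waiting-room interval, then
  hold for a pooled exam room, then (in the room) for a pooled technician.
  After the technician work-up (19±14 min) a patient dilates in the room
  with probability 0.19 (20±5 min), then may need the single shared imaging
  unit with probability 0.24 (8±4 min, room retained), then waits for their
  own provider's examination (8±6 min) and departs. The vacated room
  returns after a uniform(3, 5)-minute cleaning delay.
- **Urgent walk-in**: at most one, arriving at a uniformly random instant
  within the sessions, additional to the scheduled volume, entering at the
  *head* of every queue (priority, not preemption), and counted in all
  per-patient metrics.

Outcome metrics per replication: per-patient wait before rooming
(roomed − arrival, outside hold included), per-patient total time in
clinic, clinic-day length (last departure − morning session start, in
hours), minutes with the waiting-area count exactly at the cap, and the
maximum outside-queue length (patients only), also as a percent of
scheduled patients.

Numerical/design choices: rooms are pooled clinic-wide at 4 per provider;
technicians are pooled (the two-provider staffing shares 3); providers see
only their own panel. All per-patient random quantities are drawn up front
from one seeded generator in schedule order, and cleaning delays in
room-vacate order, so replications are bit-reproducible from their seed.
Sampling uses the same moment-matched lognormal as the generator;
a zero-SD spec returns its mean exactly, which makes small instances exactly
hand-traceable (the test suite contains event-by-event oracles for 1-, 3-
and 5-patient instances). Duration means of zero return the 0.5-minute clip
floor. Admission requires the whole arriving party (patient + guest) to fit
under the cap, so the cap is never exceeded.

## Experiment grid

Volumes of 10, 20, 25, 30 and 40 patients per provider × the two staffing
models, 100 replications per cell by default (the replication count is a
package choice; cross-replication SDs at 100 reps are small relative to the
between-volume differences). Per-replication seeds are
`master_seed + cell_index·n_reps + rep`, making cells independent and the
whole grid reproducible bit-for-bit. Between-model comparisons are Welch
t-tests per volume on replication-level means — the unit of analysis that
mean ± SD summaries across replications imply.

## Behaviour of the fitted system, and limitations

With the pandemic-era parameter set the simulated clinic is
technician-limited at high volume: rooming throughput saturates near
6.3 patients/h (one provider, two technicians at 19 min each) and
9.5 patients/h (two providers, three technicians). Consequences the
experiments reproduce: the day length grows with volume toward ~9–10 h at
40 patients/provider; waiting-area capacity exceedance is concentrated in
the two-provider model above 25 patients/provider (its technician-per-
provider ratio is lower, so roomed-but-unserved patients accumulate and
back pressure reaches the waiting area), while the one-provider model
spends almost no time at capacity even at 40 patients/provider.

A structural limitation worth stating plainly: any queueing reading of
these inputs bounds mean pre-room waits by the technician-service deficit,
so scenarios requiring substantially longer waits at the same inputs imply
an effective per-patient provider/room service time near the *unhalved*
provider phase (~16–18 min). The package deliberately keeps the documented
parameterization (halved provider phase, 8±6 min) rather than tuning toward
any external figure; users studying more congested regimes can pass their
own `SimParams`.

Other limitations: no staff breaks, no-shows or late arrivals; single-day
horizon; service durations independent of patient characteristics; one
shared imaging unit.
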