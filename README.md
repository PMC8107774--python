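# clinicflow

Cycle-time analysis of outpatient EMR timestamp logs and discrete-event
simulation of a distancing-constrained clinic day.

When a high-volume office specialty (the motivating case is a retina
clinic) restricts its waiting area for physical distancing, streamlines
exams and caps visitor numbers, two operational questions follow: how much
did each phase of the visit actually shorten, and at what future patient
volumes will the constrained clinic hit its limits? `clinicflow` answers
the first with per-encounter interval derivation from EMR event timestamps,
and the second with a discrete-event simulation (DES) fed by those
intervals.

**Who it is for:** health-services and clinical-operations researchers
working with encounter-level timestamp extracts, and anyone capacity-
planning an appointment-grid clinic under waiting-area constraints.

## The model

From each encounter's sparse timestamps the package derives visit length
(earliest stamp to the earlier of the two completion stamps),
check-in-to-technician time *W* (the waiting-room proxy), time with
technician *T*, check-in-to-provider time, and the provider phase
*P* = visit length − check-in-to-provider, halved per encounter before use
as examination time (two rooms are often flagged "in with provider"
simultaneously). Missing or negative (erroneous) stamp pairs are excluded
from interval summaries but kept in volume counts.

The fitted triple (*W*, *T*, *P*/2) parameterizes the DES: patients arrive
on 22 fifteen-minute slots (two 2 h 45 min sessions, 105-minute break),
hold outside when the 10-person waiting area is full (guests arrive with
probability 1/15 and count toward the cap), then wait *W* ~ lognormal(4, 5²),
seize a pooled room and technician (*T* ~ lognormal(19, 14²)), dilate with
probability 0.19, use the single shared imaging unit with probability 0.24,
and see their own provider (*P*/2 ~ lognormal(8, 6²)); rooms return after a
uniform(3, 5)-minute clean. The experiment layer sweeps 10–40 patients per
provider under two staffing models (1 provider/2 technicians,
2 providers/3 technicians, 4 rooms per provider) with 100 replications per
cell and Welch t-tests on replication means.

Because real encounter logs are confidential, a synthetic-EMR module
generates cohorts with era-level phase-duration, procedure-rate, age and
timestamp-missingness structure, so the whole pipeline is testable
end-to-end. See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
from clinicflow import synthetic_emr as emr, analysis, experiments

cohort = emr.generate_cohort(emr.era_preset("covid", 400, seed=7,
                                            missingness_rate=0.0))
results = analysis.ClinicFlowModel(cohort).fit()
print(results.summary())
```

```
Clinic-flow cycle-time model
============================
encounters: 400  (in-person 400)

Interval summaries (minutes; missing/erroneous stamps excluded)
           interval   n     mean       sd   median      min      max
       visit_length 400     42.9     28.7     35.4      5.5    206.9
    checkin_to_tech 400      2.9      3.6      1.7      0.5     35.5
checkin_to_provider 400     29.4     20.3     24.9      2.3    147.7
   checkin_to_image  76     39.4     18.7     33.6     13.0    105.9
     time_with_tech 400     18.5     13.7     14.8      1.6    126.9
     provider_phase 400     13.4     20.0      6.8      0.5    180.9
...
Derived simulation parameters
  waiting room 2.9 ± 3.6 min
  technician   18.5 ± 13.7 min
  examination  6.7 ± 10.0 min (provider phase halved)
  p(dilation)  0.19   p(imaging) 0.19
```

The 400-encounter pandemic-era cohort averages a 42.9-minute visit (era
target 47 ± 33), a 2.9-minute wait to the technician and a 19% dilation
rate; halving the provider phase gives the ~7-minute examination input.
Feeding the published parameter set to the experiment grid:

```python
grid = experiments.run_experiment(volumes=(10, 25, 40), n_reps=100,
                                  master_seed=42)
print(experiments.report_tables(grid)["day_length"].round(2).to_string(index=False))
```

```
 volume  1-provider_mean  1-provider_sd  2-provider_mean  2-provider_sd   p
     10             5.31           1.80             7.32           0.35 0.0
     25             7.90           0.36             8.07           0.41 0.0
     40             8.82           0.69             9.54           0.59 0.0
```

The clinic day lengthens with volume (8.8 h / 9.5 h at 40 patients per
provider); waiting-area capacity exceedance concentrates in the 2-provider
model above 25 patients per provider, whose lower technician-to-provider
ratio lets roomed-but-unserved patients back up into the waiting area.

A CLI mirrors the library:

```bash
clinicflow generate --era covid --n 400 --seed 7 --out events.csv
clinicflow analyze --events events.csv --out summary/
clinicflow simulate --providers 1 --techs 2 --volume 25 --reps 100 --seed 11
clinicflow experiment --reps 100 --seed 42 --out results/
```

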