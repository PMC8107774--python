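"""Care-phase interval derivation, cohort statistics and simulation parameters.

From sparse per-encounter timestamps this module derives the cycle-time
intervals used throughout outpatient-flow work:

* visit length — earliest stamp to the end of the visit, where the end is the
  earlier of "visit complete" and "visit complete, note pending";
* check-in-to-technician — the waiting-room-time proxy;
* time with technician — check-in to the earliest post-rooming marker, minus
  check-in-to-technician;
* check-in-to-provider and check-in-to-image-completion;
* provider phase of care — visit length minus check-in-to-provider; halved
  per encounter before use as the simulation's examination time, because two
  rooms are frequently flagged "in with provider" simultaneously.

Records with missing or erroneous (negative-interval) stamps contribute
nothing to the affected interval but still count in volume reports.

The module also exposes the comparison statistics used for era contrasts
(Welch/Student t, Pearson chi-square with family-level Bonferroni, top-box
rates with a pooled two-proportion z-test) and a statsmodels-style
:class:`ClinicFlowModel` / :class:`ClinicFlowResults` pair wrapping the whole
fit: encounter log in, interval summaries plus :class:`SimParams` out.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .synthetic_emr import EncounterRecord, read_event_log

__all__ = [
    "IntervalRecord",
    "SummaryStats",
    "SimParams",
    "visit_end_time",
    "derive_intervals",
    "intervals_frame",
    "summarize",
    "cohort_volume_report",
    "percent_change",
    "share",
    "compare_means",
    "compare_proportions_chi2",
    "bonferroni",
    "top_box_rate",
    "two_proportion_z",
    "derive_sim_params",
    "ClinicFlowModel",
    "ClinicFlowResults",
]

INTERVAL_NAMES = (
    "visit_length",
    "checkin_to_tech",
    "checkin_to_provider",
    "checkin_to_image",
    "time_with_tech",
    "provider_phase",
)


class EmptySummaryError(ValueError):
    """All values missing: the requested summary is undefined."""


@dataclass(frozen=True)
class IntervalRecord:
    """Per-encounter care-phase durations in minutes; ``None`` = missing."""

    encounter_id: str
    visit_length: float | None = None
    checkin_to_tech: float | None = None
    checkin_to_provider: float | None = None
    checkin_to_image: float | None = None
    time_with_tech: float | None = None
    provider_phase: float | None = None
    erroneous: bool = False


@dataclass(frozen=True)
class SummaryStats:
    """n / mean / SD / median / min / max of one quantity (SD uses n-1)."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    sd_defined: bool = True

    def __str__(self) -> str:
        return (
            f"{self.mean:.1f} ({self.sd:.1f})  median {self.median:.1f}  "
            f"range {self.min:.0f}-{self.max:.0f}  n={self.n}"
        )


@dataclass(frozen=True)
class SimParams:
    """Sampled-duration and branching parameters feeding the clinic DES.

    Durations are (mean, sd) minute pairs; the waiting-room time is the
    check-in-to-technician proxy, the examination time is the per-encounter
    halved provider phase.  Dilation and imaging service times have no EMR
    stamp of their own (check-in-to-image is cumulative, not a service time)
    and default to clinically plausible values; the cleaning delay is uniform
    on (3, 5) min and one guest accompanies each patient with probability
    1/15, both fixed by clinic policy rather than estimated.
    """

    waiting_room_time: tuple[float, float] = (4.0, 5.0)
    tech_time: tuple[float, float] = (19.0, 14.0)
    exam_time: tuple[float, float] = (8.0, 6.0)
    p_dilation: float = 0.19
    p_imaging: float = 0.24
    dilation_delay: tuple[float, float] = (20.0, 5.0)
    imaging_time: tuple[float, float] = (8.0, 4.0)
    cleaning_delay: tuple[float, float] = (3.0, 5.0)
    guest_probability: float = 1.0 / 15.0
    duration_family: str = "lognormal"

    def __post_init__(self) -> None:
        for name in ("p_dilation", "p_imaging", "guest_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("waiting_room_time", "tech_time", "exam_time",
                     "dilation_delay", "imaging_time"):
            m, s = getattr(self, name)
            if m < 0 or s < 0:
                raise ValueError(f"{name}: mean and sd must be nonnegative")

    @classmethod
    def covid_defaults(cls) -> "SimParams":
        """The pandemic-era parameter set: waiting room 4±5, technician
        19±14, examination 8±6 min; 19% dilation, 24% imaging."""
        return cls()

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimParams":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        for key, value in payload.items():
            if isinstance(value, list):
                payload[key] = tuple(value)
        return cls(**payload)


# ---------------------------------------------------------------------------
# Interval derivation
# ---------------------------------------------------------------------------

def visit_end_time(rec: EncounterRecord) -> float | None:
    """The earlier of the two visit-completion stamps, if either is present."""
    candidates = [
        rec.timestamps[k]
        for k in ("visit_complete", "visit_complete_note_pending")
        if k in rec.timestamps
    ]
    return min(candidates) if candidates else None


#: markers that end the technician work-up; the earliest present one is used.
_TECH_END_EVENTS = ("done_rooming", "dilating_in_waiting_room", "waiting_for_imaging")


def derive_intervals(rec: EncounterRecord) -> IntervalRecord:
    """Derive the care-phase intervals from one record's sparse timestamps.

    Any interval whose operands are missing is missing; a negative result is
    an erroneous stamp pair and is likewise recorded as missing, with the
    record flagged ``erroneous``.
    """
    ts = rec.timestamps
    erroneous = False

    def checked(value: float | None) -> float | None:
        nonlocal erroneous
        if value is not None and value < 0:
            erroneous = True
            return None
        return value

    def diff(a: float | None, b: float | None) -> float | None:
        if a is None or b is None:
            return None
        return checked(a - b)

    check_in = ts.get("check_in")
    end = visit_end_time(rec)
    earliest = min(ts.values()) if ts else None
    if end is not None and check_in is not None and end < check_in:
        # a completion stamp before check-in is an entry error, not a visit
        erroneous = True
        visit_length = None
    else:
        visit_length = diff(end, earliest)
    checkin_to_tech = diff(ts.get("in_with_technician"), check_in)
    checkin_to_provider = diff(ts.get("in_with_provider"), check_in)
    checkin_to_image = diff(ts.get("image_completion"), check_in)

    # End of technician time: earliest post-rooming marker; if none was
    # stamped, fall back to "in with technician" itself (interval 0).
    tech_end = [ts[k] for k in _TECH_END_EVENTS if k in ts]
    if not tech_end and "in_with_technician" in ts:
        tech_end = [ts["in_with_technician"]]
    time_with_tech = None
    if tech_end and check_in is not None and checkin_to_tech is not None:
        time_with_tech = checked(min(tech_end) - check_in - checkin_to_tech)

    provider_phase = None
    if visit_length is not None and checkin_to_provider is not None:
        provider_phase = checked(visit_length - checkin_to_provider)

    return IntervalRecord(
        encounter_id=rec.encounter_id,
        visit_length=visit_length,
        checkin_to_tech=checkin_to_tech,
        checkin_to_provider=checkin_to_provider,
        checkin_to_image=checkin_to_image,
        time_with_tech=time_with_tech,
        provider_phase=provider_phase,
        erroneous=erroneous,
    )


def intervals_frame(records: list[EncounterRecord]) -> pd.DataFrame:
    """Interval records for a cohort as a DataFrame (NaN = missing)."""
    rows = [dataclasses.asdict(derive_intervals(r)) for r in records]
    frame = pd.DataFrame(rows)
    return frame.astype({c: float for c in INTERVAL_NAMES})


# ---------------------------------------------------------------------------
# Summaries and cohort reports
# ---------------------------------------------------------------------------

def summarize(values, unit: str = "min") -> SummaryStats:
    """Mean/SD/median/min/max of the non-missing values (SD denominator n-1).

    A single observation has an undefined sample SD; it is reported as 0 with
    ``sd_defined=False``.
    """
    arr = np.asarray([v for v in np.ravel(np.asarray(values, dtype=float)) if not np.isnan(v)])
    if arr.size == 0:
        raise EmptySummaryError(f"no non-missing values to summarize ({unit})")
    sd_defined = arr.size > 1
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if sd_defined else 0.0,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        sd_defined=sd_defined,
    )


def percent_change(before: float, after: float) -> float | None:
    """Percent decline from ``before`` to ``after`` (integer-rounded display
    is up to the caller); ``None`` when the baseline is zero."""
    if before == 0:
        return None
    return 100.0 * (1.0 - after / before)


def share(part: float, total: float) -> float | None:
    """``part`` as a percentage of ``total``; ``None`` when total is zero."""
    if total == 0:
        return None
    return 100.0 * part / total


def cohort_volume_report(records: list[EncounterRecord]) -> pd.DataFrame:
    """Encounter counts by era and modality, with percent change across eras.

    Counts include encounters with missing timestamps.  The percent-change
    column compares ``covid`` against ``pre_covid`` within each modality and
    is rounded to integers for display (full precision in ``pct_change``).
    """
    frame = pd.DataFrame(
        {"era": [r.era for r in records], "modality": [r.modality for r in records]}
    )
    counts = frame.value_counts(["modality", "era"]).unstack(fill_value=0)
    for era in ("pre_covid", "covid"):
        if era not in counts.columns:
            counts[era] = 0
    counts = counts[["pre_covid", "covid"]]
    counts["pct_change"] = [
        percent_change(b, a) for b, a in zip(counts["pre_covid"], counts["covid"])
    ]
    counts["pct_change_display"] = [
        (None if p is None else int(round(p))) for p in counts["pct_change"]
    ]
    return counts.reset_index()


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def compare_means(group_a, group_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided independent-samples t-test (Welch by default).

    Era group sizes and variances differ widely, so unequal variances are the
    default; pass ``equal_var=True`` for the pooled Student's t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def compare_proportions_chi2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of counts.

    Yates continuity correction is off by default (the era contrasts involve
    large counts).  Bonferroni adjustment is applied at the family level by
    the caller via :func:`bonferroni`.
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table cells must be nonnegative integers")
    try:
        res = sps.chi2_contingency(arr, correction=correction)
    except ValueError as exc:
        raise ValueError(f"invalid contingency table: {exc}") from exc
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, k: int) -> float:
    """Family-level Bonferroni adjustment: min(1, p * k) for k contrasts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, p * k)


def top_box_rate(scores) -> float:
    """Fraction of 1-5 Likert responses in the top box (a rating of 5)."""
    arr = np.asarray(scores)
    if arr.size == 0:
        raise ValueError("no scores")
    if not np.isin(arr, [1, 2, 3, 4, 5]).all():
        raise ValueError("scores must lie in 1..5")
    return float(np.mean(arr == 5))


def two_proportion_z(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z statistic with two-sided p."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion (all successes or all failures)")
    z, p = proportions_ztest(
        count=np.array([p1 * n1, p2 * n2]), nobs=np.array([n1, n2]), alternative="two-sided"
    )
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Simulation parameter derivation
# ---------------------------------------------------------------------------

def derive_sim_params(
    records: list[EncounterRecord],
    intervals: pd.DataFrame | None = None,
    **fixed,
) -> SimParams:
    """Estimate :class:`SimParams` from an encounter cohort.

    Waiting-room time is the check-in-to-technician summary, technician time
    the time-with-technician summary, and examination time the per-encounter
    halved provider phase.  Branch probabilities are the observed flag
    frequencies over in-person encounters.  Fixed policy components
    (cleaning delay, guest probability, dilation/imaging service defaults)
    can be overridden through keyword arguments.
    """
    if intervals is None:
        intervals = intervals_frame(records)
    if intervals.empty:
        raise EmptySummaryError("no interval records")

    def pair(col: str, scale: float = 1.0) -> tuple[float, float]:
        values = intervals[col].dropna() * scale
        if values.empty:
            raise EmptySummaryError(f"interval {col!r} has no non-missing values")
        s = summarize(values)
        return (s.mean, s.sd)

    in_person = [r for r in records if r.modality == "in_person"]
    if not in_person:
        raise EmptySummaryError("no in-person encounters")
    p_dilation = float(np.mean([r.dilation != "none" for r in in_person]))
    p_imaging = float(np.mean([(r.oct or r.other_imaging) for r in in_person]))

    return SimParams(
        waiting_room_time=pair("checkin_to_tech"),
        tech_time=pair("time_with_tech"),
        exam_time=pair("provider_phase", scale=0.5),
        p_dilation=p_dilation,
        p_imaging=p_imaging,
        **fixed,
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ClinicFlowModel:
    """Clinic-flow cycle-time model for one encounter cohort.

    Fits era-level interval summaries and procedure rates from an EMR-style
    event log and packages the estimates as simulation inputs.

    Examples
    --------
    >>> from clinicflow import synthetic_emr as emr
    >>> cohort = emr.generate_cohort(emr.era_preset("covid", 400, seed=7))
    >>> res = ClinicFlowModel(cohort).fit()
    >>> print(res.summary())           # doctest: +SKIP
    >>> res.sim_params.exam_time       # doctest: +SKIP
    """

    def __init__(self, records: list[EncounterRecord]):
        if not records:
            raise ValueError("no encounter records")
        self.records = list(records)

    @classmethod
    def from_event_log(cls, path) -> "ClinicFlowModel":
        return cls(read_event_log(path))

    def fit(self, **fixed_params) -> "ClinicFlowResults":
        intervals = intervals_frame(self.records)
        summaries = {}
        for name in INTERVAL_NAMES:
            values = intervals[name].dropna()
            summaries[name] = summarize(values) if not values.empty else None
        in_person = [r for r in self.records if r.modality == "in_person"]
        rates = {}
        if in_person:
            rates = {
                "iop_measured": float(np.mean([r.iop_measured for r in in_person])),
                "dilation_any": float(np.mean([r.dilation != "none" for r in in_person])),
                "dilation_both_eyes": float(np.mean([r.dilation == "both_eyes" for r in in_person])),
                "injection_any": float(np.mean([r.injection != "none" for r in in_person])),
                "oct": float(np.mean([r.oct for r in in_person])),
                "other_imaging": float(np.mean([r.other_imaging for r in in_person])),
                "imaging_any": float(np.mean([(r.oct or r.other_imaging) for r in in_person])),
            }
        sim_params = None
        try:
            sim_params = derive_sim_params(self.records, intervals, **fixed_params)
        except EmptySummaryError:
            pass  # sparse cohorts still get summaries/volume reporting
        return ClinicFlowResults(self, intervals, summaries, rates, sim_params)


class ClinicFlowResults:
    """Fitted cycle-time summaries, procedure rates and simulation inputs."""

    def __init__(self, model, intervals, interval_summaries, procedure_rates, sim_params):
        self.model = model
        self.intervals = intervals
        self.interval_summaries = interval_summaries
        self.procedure_rates = procedure_rates
        self.sim_params = sim_params

    @property
    def n_encounters(self) -> int:
        return len(self.model.records)

    def volume_report(self) -> pd.DataFrame:
        return cohort_volume_report(self.model.records)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.interval_summaries.items():
            if s is None:
                continue
            rows.append(
                dict(interval=name, n=s.n, mean=s.mean, sd=s.sd,
                     median=s.median, min=s.min, max=s.max)
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Clinic-flow cycle-time model",
            "============================",
            f"encounters: {self.n_encounters}  "
            f"(in-person {sum(r.modality == 'in_person' for r in self.model.records)})",
            "",
            "Interval summaries (minutes; missing/erroneous stamps excluded)",
        ]
        frame = self.summary_frame()
        if not frame.empty:
            with pd.option_context("display.float_format", "{:8.1f}".format):
                lines.append(frame.to_string(index=False))
        if self.procedure_rates:
            lines += ["", "Procedure rates (in-person encounters)"]
            for k, v in self.procedure_rates.items():
                lines.append(f"  {k:22s} {100 * v:5.1f} %")
        if self.sim_params is not None:
            sp = self.sim_params
            lines += [
                "",
                "Derived simulation parameters",
                f"  waiting room {sp.waiting_room_time[0]:.1f} ± {sp.waiting_room_time[1]:.1f} min",
                f"  technician   {sp.tech_time[0]:.1f} ± {sp.tech_time[1]:.1f} min",
                f"  examination  {sp.exam_time[0]:.1f} ± {sp.exam_time[1]:.1f} min (provider phase halved)",
                f"  p(dilation)  {sp.p_dilation:.2f}   p(imaging) {sp.p_imaging:.2f}",
            ]
        return "\n".join(lines)

    def compare(self, other: "ClinicFlowResults", interval: str = "visit_length"):
        """Welch t-test of one interval against another fitted cohort."""
        a = self.intervals[interval].dropna()
        b = other.intervals[interval].dropna()
        return compare_means(a, b)

    def simulate(self, clinic_config=None, seed: int = 0, **config_kwargs):
        """Run one clinic-day replication using the fitted parameters."""
        from .des import ClinicConfig, run_replication

        if self.sim_params is None:
            raise EmptySummaryError("no simulation parameters could be derived")
        if clinic_config is None:
            clinic_config = ClinicConfig(**config_kwargs)
        return run_replication(clinic_config, self.sim_params, seed=seed)
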