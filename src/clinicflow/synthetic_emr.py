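"""Synthetic EMR encounter-log generation.

Real retina-clinic timestamp data are confidential, so every downstream stage
of the package (interval derivation, parameter estimation, simulation) is
exercised against synthetic encounter logs that carry the same statistical
structure: era-specific phase-duration distributions, procedure-flag rates,
truncated-normal age distributions and timestamp missingness.

Clock convention: all timestamps are minutes since the start of the day
(0 = midnight); the clinic opens at 08:00 (minute 480) by default.

Phase durations are drawn from a right-skewed nonnegative family (lognormal
by default, moment-matched to the configured mean/SD and left-clipped at
0.5 min); clinic cycle times are nonnegative and right-skewed, with medians
below means.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "EVENT_NAMES",
    "GeneratorConfig",
    "EncounterRecord",
    "era_preset",
    "generate_cohort",
    "inject_missingness",
    "expected_events",
    "has_missing_timestamps",
    "write_event_log",
    "read_event_log",
]

#: canonical timestamp column order for the event-log CSV schema
EVENT_NAMES = (
    "check_in",
    "in_with_technician",
    "done_rooming",
    "dilating_in_waiting_room",
    "waiting_for_imaging",
    "image_completion",
    "in_with_provider",
    "visit_complete",
    "visit_complete_note_pending",
    "check_out",
)

FLAG_NAMES = ("iop_measured", "dilation", "injection", "oct", "other_imaging")

ERAS = ("pre_covid", "covid")
MODALITIES = ("in_person", "telehealth")
EYE_LEVELS = ("none", "one_eye", "both_eyes")

CSV_COLUMNS = ("encounter_id", "era", "modality", "age") + EVENT_NAMES + FLAG_NAMES


class ConfigurationError(ValueError):
    """Raised when a generator or clinic configuration is invalid."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic encounter-log generator.

    ``phase_duration_specs`` maps phase name -> (mean, sd, clip) in minutes.
    Required phases: ``checkin_to_tech`` (waiting-room proxy),
    ``time_with_tech`` (rooming/technician work-up) and ``provider_phase``
    (provider portion of the visit).  Optional phases ``dilation`` and
    ``imaging`` are inserted into the timestamp chain for encounters whose
    flags select them.
    """

    era: str = "covid"
    n_encounters: int = 0
    phase_duration_specs: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    procedure_rates: dict[str, float] = field(default_factory=dict)
    age_spec: tuple[float, float, float, float] = (75.0, 13.5, 18.0, 107.0)
    missingness_rate: float = 0.0
    telehealth_fraction: float = 0.0
    duration_family: str = "lognormal"
    clinic_open_minute: float = 480.0
    clinic_span_minutes: float = 420.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise ConfigurationError(f"unknown era {self.era!r}; expected one of {ERAS}")
        if self.n_encounters < 0:
            raise ConfigurationError("n_encounters must be >= 0")
        for name, prob in self.procedure_rates.items():
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError(f"procedure rate {name}={prob} outside [0, 1]")
        for name in ("missingness_rate", "telehealth_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        for phase, (mean, sd, clip) in self.phase_duration_specs.items():
            if mean < 0 or sd < 0 or clip < 0:
                raise ConfigurationError(
                    f"phase {phase!r}: mean/sd/clip must be nonnegative"
                )
        mean, sd, lo, hi = self.age_spec
        if sd < 0 or lo > hi:
            raise ConfigurationError("invalid age_spec")


@dataclass
class EncounterRecord:
    """One clinical encounter: sparse named timestamps plus procedure flags."""

    encounter_id: str
    era: str
    modality: str
    age: float
    timestamps: dict[str, float] = field(default_factory=dict)
    iop_measured: bool = False
    dilation: str = "none"
    injection: str = "none"
    oct: bool = False
    other_imaging: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.timestamps) - set(EVENT_NAMES)
        if unknown:
            raise ValueError(f"unknown timestamp event(s): {sorted(unknown)}")
        for level_field in ("dilation", "injection"):
            if getattr(self, level_field) not in EYE_LEVELS:
                raise ValueError(f"{level_field} must be one of {EYE_LEVELS}")


# ---------------------------------------------------------------------------
# Era presets
# ---------------------------------------------------------------------------

# Pandemic-era (in-person) targets: check-in-to-technician 3 +/- 4 min,
# time with technician 19 +/- 14 min, provider phase 14 +/- 26 min (total
# visit ~47 +/- 33 min once the dilation/imaging branches are averaged in),
# age 76.8 +/- 13.4 y on [22, 102], 82% of encounters missing >= 1 stamp.
_COVID_PRESET = dict(
    phase_duration_specs={
        "checkin_to_tech": (3.0, 4.0, 0.5),
        "time_with_tech": (19.0, 14.0, 0.5),
        "provider_phase": (14.0, 26.0, 0.5),
        "dilation": (25.0, 10.0, 0.5),
        "imaging": (15.0, 8.0, 0.5),
    },
    procedure_rates={
        "iop_measured": 0.56,
        "dilation_one_eye": 0.13,
        "dilation_both_eyes": 0.06,
        "injection_one_eye": 0.69,
        "injection_both_eyes": 0.17,
        "oct": 0.19,
        "other_imaging": 0.05,
    },
    age_spec=(76.8, 13.4, 22.0, 102.0),
    missingness_rate=0.82,
)

# Pre-pandemic targets: check-in-to-technician 14 +/- 15 min, longer ancillary
# branches (dilation 87%, imaging for most visits), provider phase 18 min so
# the total visit averages ~87 +/- 35 min; age 74.3 +/- 13.6 y on [22, 107].
_PRE_COVID_PRESET = dict(
    phase_duration_specs={
        "checkin_to_tech": (14.0, 15.0, 0.5),
        "time_with_tech": (19.0, 14.0, 0.5),
        "provider_phase": (18.0, 28.0, 0.5),
        "dilation": (25.0, 10.0, 0.5),
        "imaging": (17.0, 8.0, 0.5),
    },
    procedure_rates={
        "iop_measured": 0.97,
        "dilation_one_eye": 0.25,
        "dilation_both_eyes": 0.62,
        "injection_one_eye": 0.40,
        "injection_both_eyes": 0.09,
        "oct": 0.71,
        "other_imaging": 0.04,
    },
    age_spec=(74.3, 13.6, 22.0, 107.0),
    missingness_rate=0.21,
)


def era_preset(era: str, n_encounters: int = 0, seed: int = 0, **overrides) -> GeneratorConfig:
    """Return a :class:`GeneratorConfig` preloaded with era-level targets."""
    if era == "covid":
        base = dict(_COVID_PRESET)
    elif era == "pre_covid":
        base = dict(_PRE_COVID_PRESET)
    else:
        raise ConfigurationError(f"unknown era {era!r}; expected one of {ERAS}")
    base.update(era=era, n_encounters=n_encounters, seed=seed)
    base.update(overrides)
    return GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# Duration sampling
# ---------------------------------------------------------------------------

def _draw_duration(
    mean: float, sd: float, clip: float, family: str, rng: np.random.Generator
) -> float:
    """One nonnegative duration with the given mean/SD, left-clipped.

    ``sd == 0`` degenerates to the mean exactly (before clipping), so
    deterministic scenarios stay exactly reproducible by hand.
    """
    if mean < 0:
        raise ConfigurationError("duration mean must be nonnegative")
    if sd == 0:
        value = mean
    elif family == "lognormal":
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        value = rng.lognormal(mu, math.sqrt(sigma2))
    elif family == "gamma":
        shape = (mean / sd) ** 2
        value = rng.gamma(shape, mean / shape)
    elif family == "truncated_normal":
        value = max(rng.normal(mean, sd), 0.0)
    else:
        raise ConfigurationError(f"unknown duration family {family!r}")
    return max(value, clip)


def _draw_eye_level(rng: np.random.Generator, p_one: float, p_both: float) -> str:
    u = rng.random()
    if u < p_both:
        return "both_eyes"
    if u < p_both + p_one:
        return "one_eye"
    return "none"


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> list[EncounterRecord]:
    """Generate a synthetic encounter cohort (deterministic given the seed).

    In-person timestamps are built cumulatively: check-in, a waiting-room
    interval to "in with technician", the technician work-up to "done
    rooming", optional dilation and imaging branches, then the provider
    phase ending at "visit complete" (or "visit complete, note pending",
    whichever the front desk records first).  Telehealth encounters carry no
    in-clinic timestamps and no in-clinic procedures.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.phase_duration_specs
    for required in ("checkin_to_tech", "time_with_tech", "provider_phase"):
        if config.n_encounters > 0 and required not in specs:
            raise ConfigurationError(f"phase_duration_specs missing {required!r}")

    rates = config.procedure_rates
    mean, sd, lo, hi = config.age_spec

    records: list[EncounterRecord] = []
    for i in range(config.n_encounters):
        if sd > 0:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            age = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
        else:
            age = mean
        telehealth = rng.random() < config.telehealth_fraction
        rec = EncounterRecord(
            encounter_id=f"{config.era}-{i:05d}",
            era=config.era,
            modality="telehealth" if telehealth else "in_person",
            age=age,
        )
        if telehealth:
            records.append(rec)
            continue

        rec.iop_measured = rng.random() < rates.get("iop_measured", 0.0)
        rec.dilation = _draw_eye_level(
            rng, rates.get("dilation_one_eye", 0.0), rates.get("dilation_both_eyes", 0.0)
        )
        rec.injection = _draw_eye_level(
            rng, rates.get("injection_one_eye", 0.0), rates.get("injection_both_eyes", 0.0)
        )
        rec.oct = rng.random() < rates.get("oct", 0.0)
        rec.other_imaging = rng.random() < rates.get("other_imaging", 0.0)

        def dur(phase: str) -> float:
            m, s, c = specs[phase]
            return _draw_duration(m, s, c if s > 0 else 0.0, config.duration_family, rng)

        ts = rec.timestamps
        ts["check_in"] = config.clinic_open_minute + rng.random() * config.clinic_span_minutes
        ts["in_with_technician"] = ts["check_in"] + dur("checkin_to_tech")
        ts["done_rooming"] = ts["in_with_technician"] + dur("time_with_tech")
        cursor = ts["done_rooming"]
        if rec.dilation != "none" and "dilation" in specs:
            ts["dilating_in_waiting_room"] = cursor
            cursor += dur("dilation")
        if (rec.oct or rec.other_imaging) and "imaging" in specs:
            ts["waiting_for_imaging"] = cursor
            ts["image_completion"] = cursor + dur("imaging")
            cursor = ts["image_completion"]
        ts["in_with_provider"] = cursor
        end = cursor + dur("provider_phase")
        if rng.random() < 0.4:
            # visit closed before the note is signed: the note-pending stamp
            # marks the true end, the final visit-complete stamp lands later
            ts["visit_complete_note_pending"] = end
            ts["visit_complete"] = end + rng.exponential(5.0)
        else:
            ts["visit_complete"] = end
        ts["check_out"] = end + rng.random() * 5.0
        records.append(rec)

    if config.missingness_rate > 0:
        records = inject_missingness(
            records, config.missingness_rate, seed=config.seed + 1
        )
    return records


def inject_missingness(
    records: list[EncounterRecord], rate: float, seed: int
) -> list[EncounterRecord]:
    """Blank >=1 non-check-in timestamp in exactly ``round(rate * n)`` records.

    Missingness is completely at random over the non-check-in stamps; the
    check-in stamp itself is never removed.  Returns new records; inputs are
    not mutated.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"missingness rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_affected = round(rate * len(records))
    eligible = [i for i, r in enumerate(records) if len(_removable(r)) > 0]
    if n_affected > len(eligible):
        n_affected = len(eligible)
    chosen = set(rng.choice(eligible, size=n_affected, replace=False)) if n_affected else set()

    out: list[EncounterRecord] = []
    for i, rec in enumerate(records):
        new = replace(rec, timestamps=dict(rec.timestamps))
        if i in chosen:
            removable = _removable(rec)
            k = int(rng.integers(1, len(removable) + 1))
            drop = rng.choice(len(removable), size=k, replace=False)
            for j in drop:
                del new.timestamps[removable[j]]
        out.append(new)
    return out


def _removable(rec: EncounterRecord) -> list[str]:
    return [e for e in EVENT_NAMES if e != "check_in" and e in rec.timestamps]


def expected_events(rec: EncounterRecord) -> tuple[str, ...]:
    """Timestamps an intact record of this care pathway would carry."""
    if rec.modality == "telehealth":
        return ()
    events = ["check_in", "in_with_technician", "done_rooming"]
    if rec.dilation != "none":
        events.append("dilating_in_waiting_room")
    if rec.oct or rec.other_imaging:
        events += ["waiting_for_imaging", "image_completion"]
    events += ["in_with_provider", "visit_complete", "check_out"]
    return tuple(events)


def has_missing_timestamps(rec: EncounterRecord) -> bool:
    """True if any pathway-expected timestamp is absent from the record."""
    return any(e not in rec.timestamps for e in expected_events(rec))


# ---------------------------------------------------------------------------
# Event-log CSV I/O
# ---------------------------------------------------------------------------

class EventLogParseError(ValueError):
    pass


def write_event_log(records: list[EncounterRecord], path) -> None:
    """Write records as CSV, one timestamp column per event; empty = missing."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            row = [rec.encounter_id, rec.era, rec.modality, repr(float(rec.age))]
            for event in EVENT_NAMES:
                value = rec.timestamps.get(event)
                row.append("" if value is None else repr(float(value)))
            row += [
                str(rec.iop_measured),
                rec.dilation,
                str(rec.injection),
                str(rec.oct),
                str(rec.other_imaging),
            ]
            writer.writerow(row)


def _parse_clock(text: str, line_no: int, column: str) -> float:
    """Accept minutes-since-midnight (int/float) or an HH:MM clock string."""
    if ":" in text:
        try:
            hh, mm = text.split(":")
            return int(hh) * 60.0 + float(mm)
        except ValueError:
            raise EventLogParseError(
                f"line {line_no}: bad clock value {text!r} in column {column!r}"
            ) from None
    try:
        return float(text)
    except ValueError:
        raise EventLogParseError(
            f"line {line_no}: bad numeric value {text!r} in column {column!r}"
        ) from None


def _parse_bool(text: str, line_no: int, column: str) -> bool:
    if text in ("True", "true", "1"):
        return True
    if text in ("False", "false", "0"):
        return False
    raise EventLogParseError(f"line {line_no}: bad boolean {text!r} in column {column!r}")


def read_event_log(path) -> list[EncounterRecord]:
    """Read an event-log CSV written by :func:`write_event_log`.

    Raises :class:`EventLogParseError` naming the offending column or line on
    schema or parse problems.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EventLogParseError("empty file: missing header row") from None
        unknown = [c for c in header if c not in CSV_COLUMNS]
        if unknown:
            raise EventLogParseError(f"unknown column(s): {unknown}")
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise EventLogParseError(f"missing column(s): {missing}")
        idx = {c: header.index(c) for c in CSV_COLUMNS}

        records = []
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise EventLogParseError(
                    f"line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            timestamps = {}
            for event in EVENT_NAMES:
                cell = row[idx[event]].strip()
                if cell:
                    timestamps[event] = _parse_clock(cell, line_no, event)
            era = row[idx["era"]]
            if era not in ERAS:
                raise EventLogParseError(f"line {line_no}: unknown era {era!r}")
            records.append(
                EncounterRecord(
                    encounter_id=row[idx["encounter_id"]],
                    era=era,
                    modality=row[idx["modality"]],
                    age=_parse_clock(row[idx["age"]], line_no, "age"),
                    timestamps=timestamps,
                    iop_measured=_parse_bool(row[idx["iop_measured"]], line_no, "iop_measured"),
                    dilation=row[idx["dilation"]],
                    injection=row[idx["injection"]],
                    oct=_parse_bool(row[idx["oct"]], line_no, "oct"),
                    other_imaging=_parse_bool(row[idx["other_imaging"]], line_no, "other_imaging"),
                )
            )
    return records
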