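"""Discrete-event simulation of a distancing-constrained outpatient clinic.

The model advances an event calendar through one clinic day.  Patients arrive
on a 15-minute appointment grid (11 morning and 11 afternoon slots separated
by a 105-minute break), accompanied by a guest with probability 1/15.  A
distancing cap limits the number of people in the pre-room waiting area; when
the area is full, arriving patients hold in an outside FIFO queue.  Admitted
patients spend a sampled waiting-room interval, then hold for a free exam
room and, once roomed, for a free technician.  After the technician work-up
a patient may dilate in the room and may need the single shared imaging
unit (keeping the room), then waits for their own provider's examination.
Vacated rooms return to service after a uniform cleaning delay.  Up to one
urgent walk-in can be injected at a random time, jumping to the head of
every queue.

Per-patient lifecycle stages, in order::

    arrival -> [outside hold] -> waiting-room delay -> room -> technician
            -> [dilation] -> [imaging] -> provider exam -> departure

All stochastic draws come from a single seeded generator in a fixed order
(per-patient quantities in schedule order up front, then cleaning delays in
room-vacate order), so a replication is fully reproducible from its seed.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .analysis import SimParams

__all__ = [
    "ClinicConfig",
    "PatientEntity",
    "ReplicationResult",
    "build_arrival_schedule",
    "sample_duration",
    "run_replication",
]


class UnservableConfigError(ValueError):
    """The configuration cannot serve its scheduled volume (no rooms/techs)."""


@dataclass(frozen=True)
class SessionSpec:
    """An appointment session: ``n_slots`` slots of ``slot_len`` minutes."""

    start: float
    n_slots: int = 11
    slot_len: float = 15.0


@dataclass(frozen=True)
class ClinicConfig:
    """Staffing, rooms, waiting capacity and the appointment grid.

    The default grid is 15-minute blocks over 2 h 45 min in the morning and
    afternoon with a 1 h 45 min break in between, opening at 08:00.  Rooms
    are pooled clinic-wide at ``rooms_per_provider`` per provider;
    technicians are shared across providers; each patient is bound to one
    named provider, assigned round-robin at scheduling.
    """

    n_providers: int = 1
    n_techs: int = 2
    rooms_per_provider: int = 4
    waiting_capacity: int = 10
    volume_per_provider: int = 20
    am_start: float = 480.0  # 08:00
    n_slots_per_session: int = 11
    slot_len: float = 15.0
    break_len: float = 105.0
    max_urgent: int = 1

    def __post_init__(self) -> None:
        if min(self.n_providers, self.n_techs, self.rooms_per_provider,
               self.volume_per_provider) < 0:
            raise ValueError("counts must be nonnegative")
        if self.waiting_capacity < 1:
            raise ValueError("waiting_capacity must be >= 1")
        if self.slot_len <= 0:
            raise ValueError("slot_len must be positive")
        if self.max_urgent not in (0, 1):
            raise ValueError("max_urgent must be 0 or 1")

    @property
    def n_rooms(self) -> int:
        return self.rooms_per_provider * self.n_providers

    @property
    def am_session(self) -> SessionSpec:
        return SessionSpec(self.am_start, self.n_slots_per_session, self.slot_len)

    @property
    def pm_session(self) -> SessionSpec:
        pm_start = self.am_start + self.n_slots_per_session * self.slot_len + self.break_len
        return SessionSpec(pm_start, self.n_slots_per_session, self.slot_len)

    @property
    def session_minutes(self) -> float:
        return 2 * self.n_slots_per_session * self.slot_len


@dataclass
class PatientEntity:
    """One simulated patient and their event trace (clock minutes)."""

    id: str
    provider: int
    scheduled_arrival: float
    is_urgent: bool = False
    has_guest: bool = False
    # sampled service quantities (filled before the run, in schedule order)
    waiting_delay: float = 0.0
    tech_time: float = 0.0
    needs_dilation: bool = False
    dilation_delay: float = 0.0
    needs_imaging: bool = False
    imaging_time: float = 0.0
    exam_time: float = 0.0
    # trace
    arrival: float | None = None
    waiting_entry: float | None = None
    roomed: float | None = None
    tech_done: float | None = None
    dilation_done: float | None = None
    imaging_done: float | None = None
    provider_start: float | None = None
    departure: float | None = None

    @property
    def group_size(self) -> int:
        return 2 if self.has_guest else 1


@dataclass
class ReplicationResult:
    """Outcome metrics of one simulated clinic day."""

    seed: int
    n_patients: int
    n_scheduled: int
    wait_before_room: np.ndarray
    total_time: np.ndarray
    clinic_day_length: float  # hours, last departure minus AM session start
    time_at_capacity: float  # minutes with the pre-room count at the cap
    max_outside_queue: int
    max_outside_queue_pct: float  # percent of scheduled patients
    patients: list[PatientEntity] = field(default_factory=list, repr=False)

    @property
    def mean_wait_before_room(self) -> float:
        return float(np.mean(self.wait_before_room))

    @property
    def mean_total_time(self) -> float:
        return float(np.mean(self.total_time))

    def trace_frame(self):
        import pandas as pd

        cols = ("id", "provider", "is_urgent", "has_guest", "arrival", "waiting_entry",
                "roomed", "tech_done", "dilation_done", "imaging_done",
                "provider_start", "departure")
        return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in self.patients])


# ---------------------------------------------------------------------------
# Scheduling and sampling
# ---------------------------------------------------------------------------

def build_arrival_schedule(cfg: ClinicConfig) -> list[tuple[int, float]]:
    """Deterministic (provider, scheduled-arrival) pairs on the slot grid.

    ``n_providers * volume_per_provider`` patients are assigned round-robin
    over the chronologically ordered slots, wrapping so that excess patients
    stack evenly from the earliest slot.  Providers are assigned round-robin
    in the same order.
    """
    slot_times = [
        session.start + i * session.slot_len
        for session in (cfg.am_session, cfg.pm_session)
        for i in range(session.n_slots)
    ]
    n_total = cfg.n_providers * cfg.volume_per_provider
    schedule = [
        (j % cfg.n_providers, slot_times[j % len(slot_times)]) for j in range(n_total)
    ]
    schedule.sort(key=lambda pair: pair[1])
    return schedule


def sample_duration(
    spec: tuple[float, float],
    rng: np.random.Generator,
    family: str = "lognormal",
    clip: float = 0.5,
) -> float:
    """One service duration from a (mean, sd) spec, left-clipped.

    The default family is a lognormal moment-matched to the requested mean
    and SD (clinic service times are nonnegative and right-skewed).  With
    ``sd == 0`` the mean is returned exactly, still subject to the clip so a
    zero-mean spec yields the 0.5-minute floor.
    """
    mean, sd = spec
    if mean < 0 or sd < 0:
        raise ValueError("duration mean and sd must be nonnegative")
    if sd == 0 or mean == 0:
        return max(mean, clip)
    if family == "lognormal":
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        value = rng.lognormal(mu, math.sqrt(sigma2))
    elif family == "gamma":
        shape = (mean / sd) ** 2
        value = rng.gamma(shape, mean / shape)
    elif family == "truncated_normal":
        value = max(rng.normal(mean, sd), 0.0)
    else:
        raise ValueError(f"unknown duration family {family!r}")
    return max(value, clip)


# ---------------------------------------------------------------------------
# The event-calendar engine
# ---------------------------------------------------------------------------

class _Replication:
    """State machine for one clinic-day replication."""

    def __init__(self, cfg: ClinicConfig, params: SimParams, seed: int):
        n_scheduled = cfg.n_providers * cfg.volume_per_provider
        if n_scheduled > 0 and (cfg.n_techs == 0 or cfg.n_rooms == 0 or cfg.n_providers == 0):
            raise UnservableConfigError(
                "scheduled volume > 0 requires at least one provider, technician and room"
            )
        self.cfg = cfg
        self.params = params
        self.seed = seed
        self.rng = np.random.default_rng(seed)

        self.patients = self._build_patients(n_scheduled)

        # resource state
        self.free_rooms = cfg.n_rooms
        self.free_techs = cfg.n_techs
        self.imaging_free = True
        self.provider_free = [True] * max(cfg.n_providers, 1)

        # queues (FIFO; urgent patients enter at the head)
        self.outside: deque[PatientEntity] = deque()
        self.room_queue: deque[PatientEntity] = deque()
        self.tech_queue: deque[PatientEntity] = deque()
        self.imaging_queue: deque[PatientEntity] = deque()
        self.provider_queue: list[deque[PatientEntity]] = [
            deque() for _ in range(max(cfg.n_providers, 1))
        ]

        # waiting-area occupancy accounting
        self.preroom_count = 0
        self._last_occupancy_change = cfg.am_start
        self.time_at_capacity = 0.0
        self.max_outside = 0

        self.events: list[tuple[float, int, object, PatientEntity | None]] = []
        self._seq = 0
        self.now = cfg.am_start

    # -- setup ------------------------------------------------------------

    def _build_patients(self, n_scheduled: int) -> list[PatientEntity]:
        cfg, params, rng = self.cfg, self.params, self.rng
        schedule = build_arrival_schedule(cfg)
        patients = []
        for j, (provider, when) in enumerate(schedule):
            patients.append(PatientEntity(id=f"p{j:03d}", provider=provider,
                                          scheduled_arrival=when))
        if cfg.max_urgent and n_scheduled > 0:
            # a random instant within the two arrival sessions
            u = rng.random() * cfg.session_minutes
            half = cfg.session_minutes / 2
            when = cfg.am_start + u if u < half else cfg.pm_session.start + (u - half)
            patients.append(
                PatientEntity(id="urgent", provider=int(rng.integers(cfg.n_providers)),
                              scheduled_arrival=when, is_urgent=True)
            )
            patients.sort(key=lambda p: (p.scheduled_arrival, not p.is_urgent))
        # fixed draw order: per-patient quantities in (time-sorted) schedule order
        for p in patients:
            p.has_guest = rng.random() < params.guest_probability
            p.waiting_delay = sample_duration(params.waiting_room_time, rng,
                                              params.duration_family)
            p.tech_time = sample_duration(params.tech_time, rng, params.duration_family)
            p.needs_dilation = rng.random() < params.p_dilation
            p.dilation_delay = sample_duration(params.dilation_delay, rng,
                                               params.duration_family)
            p.needs_imaging = rng.random() < params.p_imaging
            p.imaging_time = sample_duration(params.imaging_time, rng,
                                             params.duration_family)
            p.exam_time = sample_duration(params.exam_time, rng, params.duration_family)
        return patients

    # -- event plumbing ----------------------------------------------------

    def _schedule(self, when: float, handler, patient: PatientEntity | None) -> None:
        self._seq += 1
        heapq.heappush(self.events, (when, self._seq, handler, patient))

    def _set_occupancy(self, delta: int) -> None:
        if self.preroom_count == self.cfg.waiting_capacity:
            self.time_at_capacity += self.now - self._last_occupancy_change
        self._last_occupancy_change = self.now
        self.preroom_count += delta
        assert 0 <= self.preroom_count <= self.cfg.waiting_capacity

    # -- handlers ----------------------------------------------------------

    def _on_arrival(self, p: PatientEntity) -> None:
        p.arrival = self.now
        if p.is_urgent:
            self.outside.appendleft(p)
        else:
            self.outside.append(p)
        self._try_admit()
        self.max_outside = max(self.max_outside, len(self.outside))

    def _try_admit(self) -> None:
        while self.outside:
            head = self.outside[0]
            if self.preroom_count + head.group_size > self.cfg.waiting_capacity:
                break
            self.outside.popleft()
            self._set_occupancy(head.group_size)
            head.waiting_entry = self.now
            self._schedule(self.now + head.waiting_delay, self._on_waiting_done, head)

    def _on_waiting_done(self, p: PatientEntity) -> None:
        if p.is_urgent:
            self.room_queue.appendleft(p)
        else:
            self.room_queue.append(p)
        self._try_room()

    def _try_room(self) -> None:
        while self.free_rooms > 0 and self.room_queue:
            p = self.room_queue.popleft()
            self.free_rooms -= 1
            p.roomed = self.now
            self._set_occupancy(-p.group_size)  # guest leaves when patient is roomed
            if p.is_urgent:
                self.tech_queue.appendleft(p)
            else:
                self.tech_queue.append(p)
        self._try_tech()
        self._try_admit()

    def _try_tech(self) -> None:
        while self.free_techs > 0 and self.tech_queue:
            p = self.tech_queue.popleft()
            self.free_techs -= 1
            self._schedule(self.now + p.tech_time, self._on_tech_done, p)

    def _on_tech_done(self, p: PatientEntity) -> None:
        p.tech_done = self.now
        self.free_techs += 1
        self._try_tech()
        if p.needs_dilation:
            self._schedule(self.now + p.dilation_delay, self._on_dilation_done, p)
        else:
            self._to_imaging_or_provider(p)

    def _on_dilation_done(self, p: PatientEntity) -> None:
        p.dilation_done = self.now
        self._to_imaging_or_provider(p)

    def _to_imaging_or_provider(self, p: PatientEntity) -> None:
        if p.needs_imaging:
            if p.is_urgent:
                self.imaging_queue.appendleft(p)
            else:
                self.imaging_queue.append(p)
            self._try_imaging()
        else:
            self._to_provider(p)

    def _try_imaging(self) -> None:
        if self.imaging_free and self.imaging_queue:
            p = self.imaging_queue.popleft()
            self.imaging_free = False
            self._schedule(self.now + p.imaging_time, self._on_imaging_done, p)

    def _on_imaging_done(self, p: PatientEntity) -> None:
        p.imaging_done = self.now
        self.imaging_free = True
        self._try_imaging()
        self._to_provider(p)

    def _to_provider(self, p: PatientEntity) -> None:
        if self.provider_free[p.provider]:
            self._start_exam(p)
        elif p.is_urgent:
            self.provider_queue[p.provider].appendleft(p)
        else:
            self.provider_queue[p.provider].append(p)

    def _start_exam(self, p: PatientEntity) -> None:
        self.provider_free[p.provider] = False
        p.provider_start = self.now
        self._schedule(self.now + p.exam_time, self._on_exam_done, p)

    def _on_exam_done(self, p: PatientEntity) -> None:
        p.departure = self.now
        self.provider_free[p.provider] = True
        queue = self.provider_queue[p.provider]
        if queue:
            self._start_exam(queue.popleft())
        # room turns over after a cleaning delay (drawn in vacate order)
        lo, hi = self.params.cleaning_delay
        cleaning = lo + self.rng.random() * (hi - lo)
        self._schedule(self.now + cleaning, self._on_room_clean, None)

    def _on_room_clean(self, _: None) -> None:
        self.free_rooms += 1
        self._try_room()

    # -- run ---------------------------------------------------------------

    def run(self) -> ReplicationResult:
        for p in self.patients:
            self._schedule(p.scheduled_arrival, self._on_arrival, p)
        while self.events:
            self.now, _, handler, patient = heapq.heappop(self.events)
            handler(patient)

        done = [p for p in self.patients if p.departure is not None]
        assert len(done) == len(self.patients), "conservation: every arrival departs"
        waits = np.array([p.roomed - p.arrival for p in done])
        totals = np.array([p.departure - p.arrival for p in done])
        last_departure = max((p.departure for p in done), default=self.cfg.am_start)
        n_scheduled = self.cfg.n_providers * self.cfg.volume_per_provider
        return ReplicationResult(
            seed=self.seed,
            n_patients=len(done),
            n_scheduled=n_scheduled,
            wait_before_room=waits,
            total_time=totals,
            clinic_day_length=(last_departure - self.cfg.am_start) / 60.0,
            time_at_capacity=self.time_at_capacity,
            max_outside_queue=self.max_outside,
            max_outside_queue_pct=(100.0 * self.max_outside / n_scheduled
                                   if n_scheduled else 0.0),
            patients=self.patients,
        )


def run_replication(cfg: ClinicConfig, params: SimParams, seed: int = 0) -> ReplicationResult:
    """Simulate one clinic day; deterministic given ``seed``."""
    return _Replication(cfg, params, seed).run()
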