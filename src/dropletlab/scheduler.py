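"""Collision-free scheduling of droplet batches on the parallel reactor bank.

A "collision" is two distinct droplets occupying the same section of hardware
(liquid handler, main flowpath, a reactor, or the HPLC) at the same time.
The scheduler approximately minimizes makespan with the classic LPT rule
(jobs sorted by decreasing residence time), lays the chains out assuming
back-to-back droplet preparation, and then repairs collisions by scanning
the droplets in execution order and delaying each colliding droplet's
preparation — in whole multiples of the configured time unit — until its
chain fits around everything scheduled before it.  Prep starts are only ever
delayed, never advanced, and reactor assignment (earliest-free) is fixed
before shifting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .resource_model import (
    HardwareConfig,
    ReactionJob,
    ResourceInterval,
    Schedule,
    job_release_time,
    layout_job,
)

__all__ = [
    "Collision",
    "ScheduleMetrics",
    "lpt_order",
    "initial_schedule",
    "detect_collisions",
    "resolve",
    "metrics",
    "temperature_change_warnings",
]

# overlaps smaller than this are treated as zero-measure (float safety)
_EPS = 1e-9


@dataclass(frozen=True)
class Collision:
    """Positive-measure overlap of two jobs' intervals on one resource."""

    resource: str
    job_a: str
    job_b: str
    overlap_start: float
    overlap_end: float

    def __post_init__(self) -> None:
        if not self.overlap_start < self.overlap_end:
            raise ValueError("collision overlap must have positive measure")
        if self.job_a == self.job_b:
            raise ValueError("a job cannot collide with itself")


@dataclass(frozen=True)
class ScheduleMetrics:
    makespan: float
    utilization: dict[str, float]
    n_shifts: int
    total_shift_time: float


def lpt_order(jobs: list[ReactionJob]) -> list[ReactionJob]:
    """Longest-processing-time order: descending residence time, stable ties."""
    if not jobs:
        raise ValueError("cannot order an empty job list")
    return sorted(jobs, key=lambda j: -j.residence_time)


def initial_schedule(jobs: list[ReactionJob], cfg: HardwareConfig) -> Schedule:
    """Back-to-back preparation layout; may contain collisions.

    Job i's prep starts the moment the liquid handler frees from job i-1.
    Each job takes the reactor that frees earliest (reactor free = end of its
    previous occupant's rinse_b); ties go to the lowest reactor index.
    """
    if not jobs:
        raise ValueError("cannot schedule an empty job list")
    seen: set[str] = set()
    for job in jobs:
        job.validate_against(cfg)
        if job.job_id in seen:
            raise ValueError(f"duplicate job_id {job.job_id!r}")
        seen.add(job.job_id)

    prep_start: dict[str, float] = {}
    reactor_of: dict[str, int] = {}
    reactor_free = [0.0] * cfg.n_reactors  # end of rinse_b per reactor
    lh_free = 0.0
    allocations: list[ResourceInterval] = []
    for job in jobs:
        p = lh_free
        # earliest-free reactor, lowest index on ties
        r = min(range(cfg.n_reactors), key=lambda i: (reactor_free[i], i))
        prep_start[job.job_id] = p
        reactor_of[job.job_id] = r + 1
        allocations.extend(layout_job(job, cfg, p, r + 1))
        release = job_release_time(job, cfg)
        reactor_free[r] = p + release["rinse_b"]
        lh_free = p + release["prep"]
    return Schedule(
        jobs=list(jobs),
        allocations=allocations,
        reactor_of=reactor_of,
        prep_start=prep_start,
    )


def detect_collisions(schedule: Schedule) -> list[Collision]:
    """All pairwise positive-measure overlaps, ordered by start then resource.

    Empty result means the schedule is feasible.  Intervals are half-open,
    so back-to-back occupancy of a resource is legal.
    """
    by_resource: dict[str, list[ResourceInterval]] = {}
    for iv in schedule.allocations:
        by_resource.setdefault(iv.resource, []).append(iv)

    collisions: list[Collision] = []
    for resource, ivs in by_resource.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        for i, a in enumerate(ivs):
            for b in ivs[i + 1:]:
                if b.start >= a.end - _EPS:
                    break  # sorted by start: no later interval overlaps a
                if a.job_id == b.job_id:
                    continue  # one droplet may stack its own stages (rinse_b)
                lo = max(a.start, b.start)
                hi = min(a.end, b.end)
                if hi - lo > _EPS:
                    collisions.append(Collision(resource, a.job_id, b.job_id, lo, hi))
    collisions.sort(key=lambda c: (c.overlap_start, c.resource))
    return collisions


def resolve(
    schedule: Schedule,
    cfg: HardwareConfig,
    max_shift_units: int = 10**7,
) -> tuple[Schedule, int, float]:
    """Eliminate all collisions by delaying prep starts on the time-unit grid.

    Scans the droplets in execution order; each droplet whose rigid stage
    chain would collide with an already-committed (earlier) droplet has its
    preparation shifted later, one whole number of time units at a time,
    until it is collision-free against everything committed before it.  The
    sweep additionally keeps preparations in execution order (a delayed
    droplet is never leapfrogged by a later one), prep starts are only ever
    delayed relative to the back-to-back layout and only in multiples of
    ``time_unit``, and an already-feasible schedule is returned unchanged.

    Returns the feasible schedule plus the total shift count (time units)
    and total shift time.  Raises ``RuntimeError`` if any single droplet
    needs more than ``max_shift_units`` units of delay, signalling an
    infeasible configuration.

    One droplet's own stages may overlap on a resource (its rinse_a and
    transit_out when the residence is shorter than the rinse); that is not a
    collision between distinct droplets and is never "repaired".
    """
    out = schedule.copy()
    u = cfg.time_unit
    n_shifts = 0
    total_shift = 0.0

    # committed occupancy per resource: parallel start/end arrays
    busy_s: dict[str, list[float]] = {}
    busy_e: dict[str, list[float]] = {}
    prev_prep_end = -math.inf
    for job in out.jobs:
        base = out.prep_start[job.job_id]
        # order preservation: never start before the previous prep has freed
        # the liquid handler
        if prev_prep_end > base:
            extra = math.ceil((prev_prep_end - base - _EPS) / u) * u
            base += extra
        chain = layout_job(job, cfg, 0.0, out.reactor_of[job.job_id])
        rel = [(iv.resource, iv.start, iv.end) for iv in chain]
        while True:
            push = 0.0
            for resource, rs, re_ in rel:
                bs = busy_s.get(resource)
                if not bs:
                    continue
                be = busy_e[resource]
                s0, e0 = base + rs, base + re_
                for b0, b1 in zip(bs, be):
                    if s0 < b1 - _EPS and b0 < e0 - _EPS:
                        push = max(push, b1 - s0)
            if push <= _EPS:
                break
            base += math.ceil((push - _EPS) / u) * u
        delay = base - out.prep_start[job.job_id]
        if delay > 0:
            units = round(delay / u)
            if units > max_shift_units:
                raise RuntimeError(
                    f"shift budget exceeded ({max_shift_units} units for "
                    f"job {job.job_id!r}): configuration appears infeasible"
                )
            n_shifts += units
            total_shift += delay
            out.prep_start[job.job_id] = base
        for resource, rs, re_ in rel:
            busy_s.setdefault(resource, []).append(base + rs)
            busy_e.setdefault(resource, []).append(base + re_)
        prev_prep_end = base + cfg.t_prep

    allocations: list[ResourceInterval] = []
    for job in out.jobs:
        allocations.extend(
            layout_job(
                job, cfg, out.prep_start[job.job_id], out.reactor_of[job.job_id]
            )
        )
    out.allocations = allocations
    return out, n_shifts, total_shift


def metrics(
    schedule: Schedule, n_shifts: int = 0, total_shift_time: float = 0.0
) -> ScheduleMetrics:
    """Makespan and per-resource utilization of a feasible schedule."""
    if not schedule.allocations:
        raise ValueError("cannot compute metrics of an empty schedule")
    if detect_collisions(schedule):
        raise ValueError("metrics are defined only for feasible schedules")
    t0 = min(iv.start for iv in schedule.allocations)
    t1 = max(iv.end for iv in schedule.allocations)
    makespan = t1 - t0
    busy: dict[str, float] = {}
    for iv in schedule.allocations:
        busy[iv.resource] = busy.get(iv.resource, 0.0) + (iv.end - iv.start)
    utilization = {res: min(1.0, b / makespan) for res, b in busy.items()}
    return ScheduleMetrics(
        makespan=makespan,
        utilization=utilization,
        n_shifts=n_shifts,
        total_shift_time=total_shift_time,
    )


def schedule_batch(
    jobs: list[ReactionJob], cfg: HardwareConfig
) -> tuple[Schedule, ScheduleMetrics]:
    """Convenience pipeline: LPT order -> initial layout -> resolve -> metrics."""
    ordered = lpt_order(jobs)
    s, n_shifts, shift_time = resolve(initial_schedule(ordered, cfg), cfg)
    return s, metrics(s, n_shifts, shift_time)


def temperature_change_warnings(
    schedule: Schedule, threshold: float = 20.0
) -> list[str]:
    """Jobs whose reactor must change temperature by more than ``threshold``.

    The scheduler itself does not model heating/cooling; the control layer
    pauses preparation until the reactor reaches its setpoint, so large
    swings between consecutive jobs on one reactor will inflate real run
    time.  This is a post-hoc advisory only.
    """
    jobs_by_id = {j.job_id: j for j in schedule.jobs}
    per_reactor: dict[int, list[tuple[float, str]]] = {}
    for jid, r in schedule.reactor_of.items():
        per_reactor.setdefault(r, []).append((schedule.prep_start[jid], jid))
    warnings = []
    for r, entries in sorted(per_reactor.items()):
        entries.sort()
        for (_, prev), (_, cur) in zip(entries, entries[1:]):
            dT = jobs_by_id[cur].temperature - jobs_by_id[prev].temperature
            if abs(dT) > threshold:
                warnings.append(
                    f"reactor_{r}: job {cur!r} needs a {dT:+.1f} degC change "
                    f"after job {prev!r}"
                )
    return warnings
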