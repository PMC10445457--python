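"""Discrete-event execution of a schedule against the resource model.

The simulator replays a schedule as a stream of acquire/release events under
exclusive resource occupancy, acting as an oracle independent of the
scheduler's own interval-overlap check: any double-acquire is recorded as a
conflict (execution continues so all conflicts are collected).

It also reproduces the control software's temperature-pause behaviour, which
the scheduler deliberately ignores: with ``pause_for_temperature`` on, a
droplet's preparation is withheld until its assigned reactor has ramped
(linearly, at the configured heating/cooling rate) to the droplet's target
temperature.  A paused droplet's whole chain shifts rigidly, and downstream
acquisitions are re-queued first-come-first-served per resource, so pauses
only ever delay — they cannot introduce conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .resource_model import (
    HardwareConfig,
    Schedule,
    job_stage_chain,
    stage_offsets,
)
from .scheduler import Collision

__all__ = ["Event", "EventLog", "simulate", "compare"]


@dataclass(frozen=True)
class Event:
    time: float
    job_id: str
    stage: str
    resource: str
    kind: str  # "acquire" | "release"


@dataclass
class EventLog:
    events: list[Event] = field(default_factory=list)
    conflicts: list[Collision] = field(default_factory=list)
    #: reactor name -> piecewise-linear [(time, degC), ...]
    temp_traces: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    #: job_id -> actual prep start in the executed timeline
    actual_prep_start: dict[str, float] = field(default_factory=dict)

    @property
    def makespan(self) -> float:
        if not self.events:
            return 0.0
        return max(e.time for e in self.events) - min(e.time for e in self.events)


def _job_intervals(job, cfg, prep_start, reactor):
    """(stage, resource, start, end) tuples for one job's rigid chain."""
    offsets = stage_offsets(job, cfg)
    reactor_name = cfg.reactor_name(reactor)
    out = []
    for stage, resources, duration in job_stage_chain(job, cfg):
        start = prep_start + offsets[stage]
        for res in resources:
            name = reactor_name if res == "reactor" else res
            out.append((stage, name, start, start + duration))
    return out


def _replay_fixed(schedule: Schedule, cfg: HardwareConfig, log: EventLog) -> None:
    """Execute the schedule exactly as written, recording double-acquires."""
    _EPS = 1e-9
    by_resource: dict[str, list] = {}
    for iv in schedule.allocations:
        by_resource.setdefault(iv.resource, []).append(iv)
        log.events.append(Event(iv.start, iv.job_id, iv.stage, iv.resource, "acquire"))
        log.events.append(Event(iv.end, iv.job_id, iv.stage, iv.resource, "release"))
    log.events.sort(key=lambda e: (e.time, e.kind == "acquire"))
    for resource, ivs in by_resource.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        for i, a in enumerate(ivs):
            for b in ivs[i + 1:]:
                if b.start >= a.end - _EPS:
                    break
                if a.job_id == b.job_id:
                    continue
                lo, hi = max(a.start, b.start), min(a.end, b.end)
                if hi - lo > _EPS:
                    log.conflicts.append(
                        Collision(resource, a.job_id, b.job_id, lo, hi)
                    )
    log.conflicts.sort(key=lambda c: (c.overlap_start, c.resource))
    for jid, p in schedule.prep_start.items():
        log.actual_prep_start[jid] = p


def _ramp_time(t_from: float, t_to: float, cfg: HardwareConfig) -> float:
    dT = t_to - t_from
    if dT > 0:
        return dT / cfg.heat_rate
    return -dT / cfg.cool_rate


def simulate(
    schedule: Schedule,
    cfg: HardwareConfig,
    pause_for_temperature: bool = False,
    initial_temp: float | None = None,
) -> EventLog:
    """Run a schedule through the virtual platform.

    Parameters
    ----------
    pause_for_temperature
        Model the control software's behaviour of withholding droplet
        preparation until the assigned reactor has reached the droplet's
        target temperature.
    initial_temp
        Starting temperature of every reactor.  ``None`` (default) starts
        each reactor at its first droplet's target, i.e. pre-equilibrated.

    With the pause off, the schedule is replayed verbatim and any resource
    double-occupancy is recorded as a conflict.  With the pause on, jobs are
    admitted in scheduled prep order and each job's rigid chain is delayed
    (never advanced) until its reactor is at temperature and every resource
    it needs is free, so the result is conflict-free by construction.
    """
    jobs_by_id = {j.job_id: j for j in schedule.jobs}
    missing = set(schedule.prep_start) - set(jobs_by_id)
    if missing or set(jobs_by_id) - set(schedule.prep_start):
        raise ValueError("schedule job ids and prep_start keys disagree")
    for jid in jobs_by_id:
        stages = {iv.stage for iv in schedule.job_intervals(jid)}
        lacking = set(("prep", "transit_in", "rinse_a", "residence",
                       "transit_out", "rinse_b", "analysis")) - stages
        if lacking:
            raise ValueError(f"job {jid!r} is missing stages {sorted(lacking)}")

    log = EventLog()
    if not pause_for_temperature:
        _replay_fixed(schedule, cfg, log)
        _trace_temps_static(schedule, cfg, log, initial_temp)
        return log

    # ---- temperature-pause mode: rebuild the timeline job by job ----
    order = sorted(schedule.prep_start, key=lambda j: (schedule.prep_start[j], j))
    busy: dict[str, list[tuple[float, float]]] = {}
    # reactor thermal state: (time the reactor was last released, temp then)
    reactor_state: dict[int, tuple[float, float]] = {}
    traces: dict[str, list[tuple[float, float]]] = {}

    def free_at(resource: str, start: float, end: float) -> float:
        """Smallest delay >= 0 making [start+d, end+d) fit resource gaps."""
        d = 0.0
        for b0, b1 in sorted(busy.get(resource, [])):
            if start + d < b1 and b0 < end + d:
                d = b1 - start
        return d

    for jid in order:
        job = jobs_by_id[jid]
        r = schedule.reactor_of[jid]
        rname = cfg.reactor_name(r)
        sched_start = schedule.prep_start[jid]

        # temperature readiness: ramp starts when the reactor was released
        if r in reactor_state:
            t_free, temp0 = reactor_state[r]
        else:
            temp0 = job.temperature if initial_temp is None else initial_temp
            t_free = 0.0
            traces[rname] = [(0.0, temp0)]
        ramp = _ramp_time(temp0, job.temperature, cfg)
        temp_ready = t_free + ramp

        start = max(sched_start, temp_ready)
        # FIFO packing: push the rigid chain until every resource is free
        chain = _job_intervals(job, cfg, start, r)
        while True:
            extra = max(free_at(res, s, e) for _, res, s, e in chain)
            if extra <= 1e-9:
                break
            start += extra
            chain = _job_intervals(job, cfg, start, r)

        log.actual_prep_start[jid] = start
        for stage, res, s, e in chain:
            busy.setdefault(res, []).append((s, e))
            log.events.append(Event(s, jid, stage, res, "acquire"))
            log.events.append(Event(e, jid, stage, res, "release"))
        # thermal trace: hold at temp0 until release, ramp, hold at target
        if ramp > 0:
            traces[rname].append((t_free, temp0))
            traces[rname].append((t_free + ramp, job.temperature))
        rinse_b_end = max(e for st, res, s, e in chain if st == "rinse_b")
        reactor_state[r] = (rinse_b_end, job.temperature)
        traces[rname].append((rinse_b_end, job.temperature))

    log.events.sort(key=lambda e: (e.time, e.kind == "acquire"))
    log.temp_traces = {k: _dedupe(v) for k, v in traces.items()}
    return log


def _trace_temps_static(schedule, cfg, log, initial_temp):
    """Temperature traces for the no-pause replay (setpoint steps only)."""
    jobs_by_id = {j.job_id: j for j in schedule.jobs}
    per_reactor: dict[str, list[tuple[float, float]]] = {}
    for jid, r in sorted(
        schedule.reactor_of.items(), key=lambda kv: schedule.prep_start[kv[0]]
    ):
        rname = cfg.reactor_name(r)
        target = jobs_by_id[jid].temperature
        trace = per_reactor.setdefault(
            rname, [(0.0, target if initial_temp is None else initial_temp)]
        )
        t_prev, temp_prev = trace[-1]
        t_start = schedule.prep_start[jid]
        ramp = _ramp_time(temp_prev, target, cfg)
        trace.append((max(t_prev, t_start), temp_prev))
        trace.append((max(t_prev, t_start) + ramp, target))
    log.temp_traces = {k: _dedupe(v) for k, v in per_reactor.items()}


def _dedupe(trace: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for pt in trace:
        if not out or out[-1] != pt:
            out.append(pt)
    return out


@dataclass(frozen=True)
class SimulationReport:
    """Per-job deltas between scheduled and executed start times."""

    start_delta: dict[str, float]
    makespan_scheduled: float
    makespan_executed: float

    @property
    def makespan_inflation(self) -> float:
        return self.makespan_executed - self.makespan_scheduled


def compare(schedule: Schedule, log: EventLog) -> SimulationReport:
    """Attribute execution delay (temperature pauses etc.) per job."""
    if set(log.actual_prep_start) != set(schedule.prep_start):
        raise ValueError("event log does not match the schedule's job ids")
    deltas = {
        jid: log.actual_prep_start[jid] - schedule.prep_start[jid]
        for jid in schedule.prep_start
    }
    t0 = min(iv.start for iv in schedule.allocations)
    t1 = max(iv.end for iv in schedule.allocations)
    return SimulationReport(
        start_delta=deltas,
        makespan_scheduled=t1 - t0,
        makespan_executed=log.makespan,
    )
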