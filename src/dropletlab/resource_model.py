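"""Hardware abstraction for the parallel droplet-reactor platform.

The platform moves each reaction droplet through a fixed chain of hardware
operations: preparation on a liquid handler, transit through a shared main
flowpath into one of a bank of parallel reactors, a residence period, transit
back out to HPLC sampling, and analysis.  Every transit is immediately
followed by a rinse/vent of the flowpath; the rinse that follows the outbound
transit also rinses the droplet's reactor.  The liquid handler, the main
flowpath and the HPLC are bottlenecks that only one droplet may occupy at a
time, which is what makes scheduling nontrivial.

This module defines the configuration, job and interval types that both the
scheduler and the discrete-event simulator consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "HardwareConfig",
    "ReactionJob",
    "ResourceInterval",
    "Schedule",
    "STAGES",
    "job_stage_chain",
    "layout_job",
    "single_job_span",
]

#: Canonical stage order of one droplet's lifecycle.
STAGES = (
    "prep",
    "transit_in",
    "rinse_a",
    "residence",
    "transit_out",
    "rinse_b",
    "analysis",
)


@dataclass(frozen=True)
class HardwareConfig:
    """Timing and capacity parameters of the platform.

    All durations are in seconds.  ``time_unit`` is the granularity of the
    scheduler's shift operation; stage durations need not be multiples of it.
    ``heat_rate``/``cool_rate`` (degC/s) are used only by the simulator's
    temperature-pause model, never by the scheduler.
    """

    n_reactors: int = 10
    t_prep: float = 120.0
    t_transit_in: float = 60.0
    t_rinse_a: float = 90.0
    t_transit_out: float = 60.0
    t_rinse_b: float = 120.0
    t_hplc: float = 300.0
    time_unit: float = 1.0
    temp_min: float = 0.0
    temp_max: float = 200.0
    heat_rate: float = 1.0
    cool_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_reactors < 1:
            raise ValueError(f"n_reactors must be >= 1, got {self.n_reactors}")
        for name in ("t_prep", "t_transit_in", "t_rinse_a", "t_transit_out",
                     "t_rinse_b", "t_hplc", "time_unit", "heat_rate", "cool_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.temp_min < self.temp_max:
            raise ValueError(
                f"temp_min ({self.temp_min}) must be < temp_max ({self.temp_max})"
            )

    def reactor_name(self, index: int) -> str:
        if not 1 <= index <= self.n_reactors:
            raise ValueError(f"reactor index {index} outside 1..{self.n_reactors}")
        return f"reactor_{index}"

    def resources(self) -> list[str]:
        """All resource names: shared bottlenecks plus the reactor bank."""
        return ["liquid_handler", "main_flowpath", "hplc"] + [
            self.reactor_name(i) for i in range(1, self.n_reactors + 1)
        ]


@dataclass(frozen=True)
class ReactionJob:
    """Specification of one reaction droplet.

    ``payload`` carries arbitrary condition information (concentrations,
    catalyst, base, ...) through to the virtual bench or optimizer; the
    scheduler ignores it.
    """

    job_id: str
    temperature: float
    residence_time: float
    mode: str = "thermal"
    led_power: float | None = None
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("thermal", "photochemical"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.residence_time <= 0:
            raise ValueError(
                f"residence_time must be > 0, got {self.residence_time}"
            )
        if self.mode == "photochemical":
            if self.led_power is None or not 0.0 <= self.led_power <= 1.0:
                raise ValueError("photochemical jobs need led_power in [0, 1]")

    def validate_against(self, cfg: HardwareConfig) -> None:
        if not cfg.temp_min <= self.temperature <= cfg.temp_max:
            raise ValueError(
                f"job {self.job_id}: temperature {self.temperature} outside "
                f"[{cfg.temp_min}, {cfg.temp_max}]"
            )


@dataclass(frozen=True)
class ResourceInterval:
    """Half-open occupancy interval [start, end) of one resource by one job."""

    resource: str
    start: float
    end: float
    job_id: str
    stage: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"interval must have start < end, got [{self.start}, {self.end})"
            )

    def overlaps(self, other: "ResourceInterval") -> bool:
        """Positive-measure overlap on the same resource."""
        return (
            self.resource == other.resource
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Schedule:
    """Timed allocation of every job's stage chain to platform resources."""

    jobs: list[ReactionJob]
    allocations: list[ResourceInterval]
    reactor_of: dict[str, int]
    prep_start: dict[str, float]

    def job_intervals(self, job_id: str) -> list[ResourceInterval]:
        return [iv for iv in self.allocations if iv.job_id == job_id]

    def copy(self) -> "Schedule":
        return Schedule(
            jobs=list(self.jobs),
            allocations=list(self.allocations),
            reactor_of=dict(self.reactor_of),
            prep_start=dict(self.prep_start),
        )


def job_stage_chain(
    job: ReactionJob, cfg: HardwareConfig
) -> list[tuple[str, tuple[str, ...], float]]:
    """Canonical stage chain of one droplet as (stage, resources, duration).

    The chain is: prep (liquid handler) -> transit_in (main flowpath) ->
    rinse_a (main flowpath only) -> residence (assigned reactor) ->
    transit_out (main flowpath) -> rinse_b (main flowpath AND the reactor) ->
    analysis (HPLC).  The reactor placeholder ``"reactor"`` is substituted
    with a concrete reactor name at layout time.

    rinse_a runs concurrently with the residence period (disjoint hardware),
    and HPLC analysis runs concurrently with rinse_b, so a single job's span
    is the sum of stage durations minus those two overlaps.
    """
    job.validate_against(cfg)
    return [
        ("prep", ("liquid_handler",), cfg.t_prep),
        ("transit_in", ("main_flowpath",), cfg.t_transit_in),
        ("rinse_a", ("main_flowpath",), cfg.t_rinse_a),
        ("residence", ("reactor",), job.residence_time),
        ("transit_out", ("main_flowpath",), cfg.t_transit_out),
        ("rinse_b", ("main_flowpath", "reactor"), cfg.t_rinse_b),
        ("analysis", ("hplc",), cfg.t_hplc),
    ]


def stage_offsets(job: ReactionJob, cfg: HardwareConfig) -> dict[str, float]:
    """Start offset of each stage relative to prep start.

    Immediacy constraints make every offset rigid: the droplet enters its
    reactor at the end of transit_in (so residence overlaps rinse_a) and
    analysis starts at the end of transit_out (overlapping rinse_b).
    """
    t0 = 0.0
    off = {"prep": t0}
    off["transit_in"] = t0 + cfg.t_prep
    off["rinse_a"] = off["transit_in"] + cfg.t_transit_in
    off["residence"] = off["transit_in"] + cfg.t_transit_in
    off["transit_out"] = off["residence"] + job.residence_time
    off["rinse_b"] = off["transit_out"] + cfg.t_transit_out
    off["analysis"] = off["transit_out"] + cfg.t_transit_out
    return off


def layout_job(
    job: ReactionJob, cfg: HardwareConfig, prep_start: float, reactor: int
) -> list[ResourceInterval]:
    """All resource intervals of one job given its prep start and reactor."""
    chain = job_stage_chain(job, cfg)
    offsets = stage_offsets(job, cfg)
    reactor_name = cfg.reactor_name(reactor)
    intervals: list[ResourceInterval] = []
    for stage, resources, duration in chain:
        start = prep_start + offsets[stage]
        for res in resources:
            name = reactor_name if res == "reactor" else res
            intervals.append(
                ResourceInterval(name, start, start + duration, job.job_id, stage)
            )
    return intervals


def single_job_span(job: ReactionJob, cfg: HardwareConfig) -> float:
    """Elapsed time of one droplet run from prep start to last release."""
    intervals = layout_job(job, cfg, 0.0, 1)
    return max(iv.end for iv in intervals) - min(iv.start for iv in intervals)


def job_release_time(job: ReactionJob, cfg: HardwareConfig) -> dict[str, float]:
    """End offset (relative to prep start) of each stage; convenience."""
    offsets = stage_offsets(job, cfg)
    chain = {s: d for s, _, d in job_stage_chain(job, cfg)}
    return {s: offsets[s] + chain[s] for s in offsets}
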