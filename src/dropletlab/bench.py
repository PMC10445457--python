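"""Virtual bench: seeded synthetic stand-ins for the physical platform.

Three generators make every other module testable without hardware or
downloads:

* SNAr kinetic profiles — concentration decays of 4-fluoronitrobenzene
  reacting with 1-methylpiperazine, integrated from the third-order rate law
  with rate constants measured on the real platform (3.32, 5.00, 7.90 and
  10.6 x 10^-4 M^-2 s^-1 at 60/70/80/90 degC) and multiplicative HPLC-like
  noise.
* A Buchwald-Hartwig amination response surface over catalyst, base,
  temperature and residence time, qualitatively faithful to the campaign
  findings: the best cell is (tBuBrettPhos Pd G3, DBU), performance rises
  monotonically with temperature up to the top of the range, residence time
  is nearly flat, and a XantPhos-like catalyst is essentially dead.
* Random droplet job batches for scheduler property tests.

Noise is multiplicative Gaussian with a 3% relative standard deviation by
default, matching the platform's replicate reproducibility and comfortably
inside its <5% design criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .kinetics import (
    ConcentrationState,
    KineticDataset,
    KineticGroup,
    RateLawParams,
    integrate_rate_law,
)
from .optimizer import DomainSpec, Observation
from .resource_model import ReactionJob

__all__ = [
    "SNArGroundTruth",
    "BHASurface",
    "MeasurementModel",
    "generate_snar_dataset",
    "campaign_design",
    "bha_objective",
    "generate_job_batch",
    "DEFAULT_SNAR_KS",
    "BHA_DOMAIN",
]

#: Measured SNAr rate constants (M^-2 s^-1) by temperature (degC).
DEFAULT_SNAR_KS: dict[float, float] = {
    60.0: 3.32e-4,
    70.0: 5.00e-4,
    80.0: 7.90e-4,
    90.0: 10.6e-4,
}


@dataclass(frozen=True)
class SNArGroundTruth:
    """Known rate constants and stoichiometry the SNAr generator samples from."""

    k_by_temp: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_SNAR_KS)
    )
    order_arf: float = 1.0
    order_amine: float = 2.0
    amine_stoich: float = 2.0

    def __post_init__(self) -> None:
        temps = sorted(self.k_by_temp)
        ks = [self.k_by_temp[t] for t in temps]
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("rate constants must increase with temperature")

    def params_at(self, temperature_c: float) -> RateLawParams:
        return RateLawParams(
            k=self.k_by_temp[temperature_c],
            order_arf=self.order_arf,
            order_amine=self.order_amine,
            amine_stoich=self.amine_stoich,
        )


def campaign_design(
    arf0_70: tuple[float, float] = (0.8, 1.04),
    arf0_single: float = 1.04,
    amine0: float = 2.08,
    times_min: Sequence[float] = (5, 10, 15, 25, 40),
) -> list[tuple[float, ConcentrationState, tuple[float, ...]]]:
    """The kinetics campaign design: (temperature, c0, times_s) conditions.

    Two initial ArF concentrations at 70 degC plus a single concentration at
    60, 80 and 90 degC, each sampled at residence times of 5, 10, 15, 25 and
    40 minutes — 25 droplet reactions in total.
    """
    times_s = tuple(60.0 * t for t in times_min)
    design = [
        (70.0, ConcentrationState(arf=a0, amine=amine0), times_s)
        for a0 in arf0_70
    ]
    design += [
        (t, ConcentrationState(arf=arf0_single, amine=amine0), times_s)
        for t in (60.0, 80.0, 90.0)
    ]
    return design


def generate_snar_dataset(
    truth: SNArGroundTruth,
    design: list[tuple[float, ConcentrationState, tuple[float, ...]]],
    noise_sd: float = 0.01,
    seed: int = 0,
) -> KineticDataset:
    """Integrate the rate law per condition and add relative Gaussian noise.

    Noise is multiplicative (measured = true * (1 + eps), eps ~ N(0, sd)),
    clipped at zero; ``noise_sd = 0`` reproduces the exact model decays.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    groups = []
    for temperature_c, c0, times_s in design:
        if temperature_c not in truth.k_by_temp:
            raise ValueError(f"no ground-truth k at {temperature_c} degC")
        states = integrate_rate_law(truth.params_at(temperature_c), c0, times_s)
        arf = np.array([s.arf for s in states])
        if noise_sd > 0:
            arf = arf * (1.0 + rng.normal(0.0, noise_sd, arf.size))
        arf = np.maximum(arf, 0.0)
        groups.append(
            KineticGroup(
                temperature_c=temperature_c,
                c0=c0,
                times_s=tuple(times_s),
                arf_measured=tuple(float(a) for a in arf),
            )
        )
    return KineticDataset(groups)


# --------------------------------------------------------------------- BHA

#: The amination campaign's search domain.
BHA_DOMAIN = DomainSpec(
    continuous=(
        ("temperature", 50.0, 100.0),
        ("residence_time", 5.0, 60.0),
    ),
    categorical=(
        ("catalyst", ("tBuBrettPhos Pd G3", "tBuXPhos Pd G3")),
        ("base", ("DBU", "BTMG")),
    ),
)


@dataclass(frozen=True)
class BHASurface:
    """Deterministic Buchwald-Hartwig response surface in [0, 1].

    The response factorizes into catalyst and base multipliers, a monotone
    temperature term maximal at ``temp_range[1]``, and a nearly flat
    residence-time term.  The known optimum is (tBuBrettPhos Pd G3, DBU) at
    the maximum temperature.  ``XantPhos Pd G3`` is included as a dead
    catalyst for campaigns that offer it.
    """

    catalyst_mult: dict[str, float] = field(
        default_factory=lambda: {
            "tBuBrettPhos Pd G3": 1.0,
            "tBuXPhos Pd G3": 0.7,
            "XantPhos Pd G3": 0.02,
        }
    )
    base_mult: dict[str, float] = field(
        default_factory=lambda: {"DBU": 1.0, "BTMG": 0.8}
    )
    temp_range: tuple[float, float] = (50.0, 100.0)
    time_range: tuple[float, float] = (5.0, 60.0)
    temp_floor: float = 0.4     # response fraction at the low-temperature end
    time_slope: float = 0.05    # residence time moves the response <= 5%

    def value(self, x: dict[str, Any]) -> float:
        """Noise-free response at a condition record."""
        t_lo, t_hi = self.temp_range
        u = (float(x["temperature"]) - t_lo) / (t_hi - t_lo)
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"temperature {x['temperature']} outside surface range")
        f_t = self.temp_floor + (1.0 - self.temp_floor) * u
        r_lo, r_hi = self.time_range
        v = (float(x["residence_time"]) - r_lo) / (r_hi - r_lo)
        if not 0.0 <= v <= 1.0:
            raise ValueError(
                f"residence_time {x['residence_time']} outside surface range"
            )
        f_r = (1.0 - self.time_slope) + self.time_slope * v
        return (
            self.catalyst_mult[x["catalyst"]] * self.base_mult[x["base"]]
            * f_t * f_r
        )

    def optimum(self) -> float:
        """The surface's known maximal (noise-free) response."""
        return (
            max(self.catalyst_mult.values()) * max(self.base_mult.values())
        )  # f_t = f_r = 1 at (temp_max, time_max)


@dataclass(frozen=True)
class MeasurementModel:
    """HPLC-like measurement: relative Gaussian noise, internal-standard ratio."""

    internal_standard_area: float = 1e5
    relative_noise_sd: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_noise_sd < 0.05:
            raise ValueError("relative noise must be below the 5% design criterion")
        if self.internal_standard_area <= 0:
            raise ValueError("internal standard area must be positive")


def bha_objective(
    x: dict[str, Any],
    surface: BHASurface,
    mm: MeasurementModel,
    rng: np.random.Generator | None = None,
) -> Observation:
    """Evaluate one condition on the virtual amination bench.

    The raw product peak area is the surface value scaled by the internal
    standard area with multiplicative noise; the reported objective is the
    ratio to the internal standard, so it is invariant to the standard's
    absolute scale.
    """
    if rng is None:
        rng = np.random.default_rng(mm.rng_seed)
    true = surface.value(x)
    eps = rng.normal(0.0, mm.relative_noise_sd) if mm.relative_noise_sd else 0.0
    product_area = true * mm.internal_standard_area * (1.0 + eps)
    y = product_area / mm.internal_standard_area
    return Observation(x=dict(x), y=float(y))


# ------------------------------------------------------------------- jobs

def generate_job_batch(
    n: int,
    seed: int = 0,
    residence_range_s: tuple[float, float] = (300.0, 2400.0),
    temp_range_c: tuple[float, float] = (25.0, 150.0),
    p_photochemical: float = 0.0,
) -> list[ReactionJob]:
    """Random droplet batch for scheduler/simulator property tests."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = residence_range_s
    t_lo, t_hi = temp_range_c
    jobs = []
    for i in range(n):
        mode = "photochemical" if rng.random() < p_photochemical else "thermal"
        jobs.append(
            ReactionJob(
                job_id=f"job_{i:03d}",
                temperature=float(t_lo + rng.random() * (t_hi - t_lo)),
                residence_time=float(lo if hi == lo else lo + rng.random() * (hi - lo)),
                mode=mode,
                led_power=float(rng.random()) if mode == "photochemical" else None,
            )
        )
    return jobs
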