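"""Rate-law integration, rate-constant fitting and Eyring analysis.

The model reaction is the nucleophilic aromatic substitution (SNAr) of
4-fluoronitrobenzene (ArF, the limiting reagent) with 1-methylpiperazine
(R2NH) in acetonitrile, third order overall:

    r = k [ArF] [R2NH]^2

Concentration profiles of the aryl halide are fit per temperature by
nonlinear least squares against the integrated rate law, jointly across all
initial-concentration groups at that temperature.  The temperature dependence
of k is then analysed with the Eyring equation,

    ln(k/T) = -dH/(R T) + ln(kB/h) + dS/R,

linearised as ordinary least squares of ln(k/T) on 1/T, giving the activation
enthalpy dH (kJ/mol) from the slope and activation entropy dS (J/mol/K) from
the intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "RateLawParams",
    "ConcentrationState",
    "KineticGroup",
    "KineticDataset",
    "EyringFit",
    "integrate_rate_law",
    "fit_rate_constant",
    "eyring_regression",
    "predict_k",
]

K_B = constants.k          # Boltzmann constant, J/K
H_PLANCK = constants.h     # Planck constant, J s
R_GAS = constants.R        # gas constant, J/(mol K)

_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class RateLawParams:
    """Parameters of the r = k [ArF]^a [R2NH]^b rate law.

    Orders default to the experimentally established a=1, b=2.  The amine is
    consumed ``amine_stoich`` mol per mol ArF (default 2: one equivalent as
    nucleophile, one scavenging the liberated HF).
    """

    k: float
    order_arf: float = 1.0
    order_amine: float = 2.0
    amine_stoich: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rate constant must be >= 0, got {self.k}")


@dataclass(frozen=True)
class ConcentrationState:
    """Species concentrations (M) at one instant."""

    arf: float
    amine: float
    product: float = 0.0

    def __post_init__(self) -> None:
        if self.arf < 0 or self.amine < 0 or self.product < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class KineticGroup:
    """One condition: temperature, initial state, and measured ArF decay."""

    temperature_c: float
    c0: ConcentrationState
    times_s: tuple[float, ...]
    arf_measured: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.arf_measured):
            raise ValueError("times and measurements must align")
        if any(b <= a for a, b in zip(self.times_s, self.times_s[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass
class KineticDataset:
    groups: list[KineticGroup] = field(default_factory=list)

    def at_temperature(self, temperature_c: float) -> "KineticDataset":
        return KineticDataset(
            [g for g in self.groups if g.temperature_c == temperature_c]
        )

    def temperatures(self) -> list[float]:
        return sorted({g.temperature_c for g in self.groups})


def integrate_rate_law(
    params: RateLawParams,
    c0: ConcentrationState,
    times: np.ndarray | list[float],
) -> list[ConcentrationState]:
    """Integrate d[ArF]/dt = -k [ArF]^a [R2NH]^b from ``c0`` at ``times``.

    The amine depletes at ``amine_stoich`` times the ArF rate; the product
    accumulates 1:1 with consumed ArF, so mass balance
    arf + product = arf0 + product0 holds to solver tolerance.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times.size and times[0] < 0:
        raise ValueError("times must be non-negative")
    arf_t = _integrate_arf(params, c0, times)
    consumed = c0.arf - arf_t
    amine_t = np.maximum(c0.amine - params.amine_stoich * consumed, 0.0)
    return [
        ConcentrationState(
            arf=max(a, 0.0), amine=am, product=c0.product + max(c, 0.0)
        )
        for a, am, c in zip(arf_t, amine_t, consumed)
    ]


def _integrate_arf(
    params: RateLawParams, c0: ConcentrationState, times: np.ndarray
) -> np.ndarray:
    if times.size == 0:
        return np.empty(0)
    if params.k == 0.0:
        return np.full(times.size, c0.arf)

    def rhs(_t, y):
        arf = max(y[0], 0.0)
        amine = max(y[1], 0.0)
        r = params.k * arf**params.order_arf * amine**params.order_amine
        return [-r, -params.amine_stoich * r]

    t_eval = times
    t0 = 0.0
    sol = solve_ivp(
        rhs,
        (t0, float(times[-1])) if times[-1] > t0 else (t0, t0 + 1e-12),
        [c0.arf, c0.amine],
        t_eval=t_eval,
        method="LSODA",
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"rate-law integration failed: {sol.message}")
    return sol.y[0]


def fit_rate_constant(
    data: KineticDataset,
    p0: float = 1e-4,
    orders: tuple[float, float] = (1.0, 2.0),
    amine_stoich: float = 2.0,
) -> tuple[float, float]:
    """Fit k (M^-2 s^-1) to all groups of a one-temperature dataset.

    Nonlinear least squares of the measured ArF concentrations against the
    integrated rate law, jointly across initial-concentration groups.  k is
    parametrised on a log scale to enforce positivity; a flat dataset (no
    measurable decay) is reported as k = 0 with an infinite standard error.

    Returns
    -------
    (k, se)
        Point estimate and asymptotic standard error from the Jacobian.
    """
    if not data.groups:
        raise ValueError("empty dataset")
    temps = {g.temperature_c for g in data.groups}
    if len(temps) != 1:
        raise ValueError(f"expected a single temperature, got {sorted(temps)}")
    if any(len(g.times_s) < 1 for g in data.groups):
        raise ValueError("every group needs at least one timepoint")
    n_points = sum(len(g.times_s) for g in data.groups)
    if n_points < 3:
        raise ValueError("need at least 3 timepoints in total")
    if p0 <= 0:
        raise ValueError("initial guess must be positive")

    measured = np.concatenate([np.asarray(g.arf_measured) for g in data.groups])
    # flat data: no decay signal at all -> k pinned at zero
    decays = [
        g.arf_measured[0] - min(g.arf_measured) for g in data.groups
    ]
    if all(abs(d) < 1e-12 for d in decays):
        return 0.0, math.inf

    def residuals(log_k: np.ndarray) -> np.ndarray:
        p = RateLawParams(
            k=float(np.exp(log_k[0])),
            order_arf=orders[0],
            order_amine=orders[1],
            amine_stoich=amine_stoich,
        )
        pred = np.concatenate(
            [
                np.array([s.arf for s in integrate_rate_law(p, g.c0, g.times_s)])
                for g in data.groups
            ]
        )
        return pred - measured

    fit = least_squares(residuals, x0=[math.log(p0)], method="lm", xtol=1e-12)
    if not fit.success:
        raise RuntimeError(f"rate-constant fit did not converge: {fit.message}")
    k = float(np.exp(fit.x[0]))
    # delta method: var(k) = k^2 var(log k)
    dof = max(measured.size - 1, 1)
    s2 = float(fit.fun @ fit.fun) / dof
    jtj = float(np.sum(fit.jac**2))
    se_logk = math.sqrt(s2 / jtj) if jtj > 0 else math.inf
    return k, k * se_logk


@dataclass(frozen=True)
class EyringFit:
    """Result of the linearised Eyring regression ln(k/T) = a + b/T."""

    slope: float          # K (equals -dH/R)
    intercept: float      # dimensionless (equals ln(kB/h) + dS/R)
    dH: float             # kJ/mol
    dS: float             # J/(mol K)
    se_dH: float          # kJ/mol
    se_dS: float          # J/(mol K)
    n: int

    k_B: float = K_B
    h: float = H_PLANCK
    R: float = R_GAS


def eyring_regression(ks: list[tuple[float, float]]) -> EyringFit:
    """OLS of ln(k/T) on 1/T for (temperature K, k) pairs.

    Activation parameters follow from dH = -slope*R (J/mol, reported in
    kJ/mol) and dS = (intercept - ln(kB/h))*R; standard errors propagate
    linearly from the slope/intercept errors.  With exactly two temperatures
    the fit reduces to the two-point closed form and the errors are
    undefined (reported as nan).
    """
    if len(ks) < 2:
        raise ValueError("Eyring regression needs at least 2 temperatures")
    T = np.array([t for t, _ in ks], dtype=float)
    k = np.array([kk for _, kk in ks], dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive kelvin")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    if np.unique(T).size < 2:
        raise ValueError("need at least 2 distinct temperatures")

    x = 1.0 / T
    y = np.log(k / T)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    if n > 2:
        s2 = float(resid @ resid) / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se_intercept = math.sqrt(cov[0, 0])
        se_slope = math.sqrt(cov[1, 1])
    else:
        se_intercept = se_slope = math.nan

    dH = -slope * R_GAS / 1000.0
    dS = (intercept - math.log(K_B / H_PLANCK)) * R_GAS
    return EyringFit(
        slope=slope,
        intercept=intercept,
        dH=dH,
        dS=dS,
        se_dH=se_slope * R_GAS / 1000.0,
        se_dS=se_intercept * R_GAS,
        n=n,
    )


def predict_k(fit: EyringFit, temperature_k: float) -> float:
    """Rate constant on the fitted Eyring line at ``temperature_k``."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive kelvin")
    return temperature_k * math.exp(fit.intercept + fit.slope / temperature_k)


def eyring_k(dH_kJ_mol: float, dS_J_mol_K: float, temperature_k: float) -> float:
    """Forward Eyring equation: k = (kB T / h) exp(-dH/RT) exp(dS/R)."""
    T = temperature_k
    return (
        K_B * T / H_PLANCK
        * math.exp(-dH_kJ_mol * 1000.0 / (R_GAS * T))
        * math.exp(dS_J_mol_K / R_GAS)
    )
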