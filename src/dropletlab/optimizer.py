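"""Ask-tell Bayesian optimization over mixed categorical/continuous domains.

Mirrors the closed-loop reaction-optimization protocol used on the droplet
platform: categorical variables (catalyst, base) are one-hot encoded,
continuous variables (temperature, residence time) are min-max scaled, a
Gaussian-process surrogate (Matern-5/2) is fit to the encoded history, and
each proposal is the maximizer over a random candidate pool of an
acquisition function drawn from {UCB, EI, Thompson sampling}.  The sampling
weights over acquisitions adapt multiplicatively toward the acquisitions
whose proposals have improved the incumbent, with a floor so that none
starves.  Everything is seeded and deterministic given the seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

__all__ = [
    "DomainSpec",
    "Observation",
    "OptimizerState",
    "MixedBayesOptimizer",
]

ACQUISITIONS = ("ucb", "ei", "thompson")


@dataclass(frozen=True)
class DomainSpec:
    """Mixed optimization domain.

    ``continuous``: (name, low, high) triples; ``categorical``: (name,
    levels) pairs.  Names must be unique across both groups.
    """

    continuous: tuple[tuple[str, float, float], ...] = ()
    categorical: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, *_ in self.continuous] + [n for n, _ in self.categorical]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if not names:
            raise ValueError("domain must have at least one variable")
        for name, lo, hi in self.continuous:
            if not lo < hi:
                raise ValueError(f"{name}: low ({lo}) must be < high ({hi})")
        for name, levels in self.categorical:
            if len(levels) < 1:
                raise ValueError(f"{name}: needs at least one level")
            if len(set(levels)) != len(levels):
                raise ValueError(f"{name}: duplicate levels")

    @property
    def encoded_dim(self) -> int:
        return len(self.continuous) + sum(len(lv) for _, lv in self.categorical)

    def contains(self, x: dict[str, Any]) -> bool:
        try:
            self.validate(x)
        except ValueError:
            return False
        return True

    def validate(self, x: dict[str, Any]) -> None:
        for name, lo, hi in self.continuous:
            if name not in x:
                raise ValueError(f"missing variable {name!r}")
            if not lo <= float(x[name]) <= hi:
                raise ValueError(f"{name}={x[name]} outside [{lo}, {hi}]")
        for name, levels in self.categorical:
            if name not in x:
                raise ValueError(f"missing variable {name!r}")
            if x[name] not in levels:
                raise ValueError(f"{name}={x[name]!r} not in {levels}")
        extra = set(x) - {n for n, *_ in self.continuous} - {
            n for n, _ in self.categorical
        }
        if extra:
            raise ValueError(f"unknown variables {sorted(extra)}")


def encode(x: dict[str, Any], domain: DomainSpec) -> np.ndarray:
    """Min-max scale continuous variables, one-hot expand categoricals."""
    domain.validate(x)
    parts: list[float] = []
    for name, lo, hi in domain.continuous:
        parts.append((float(x[name]) - lo) / (hi - lo))
    for name, levels in domain.categorical:
        idx = levels.index(x[name])
        block = [0.0] * len(levels)
        block[idx] = 1.0
        parts.extend(block)
    return np.array(parts)


def decode(v: np.ndarray, domain: DomainSpec) -> dict[str, Any]:
    """Inverse of :func:`encode`; one-hot blocks decode by argmax."""
    if v.shape != (domain.encoded_dim,):
        raise ValueError(
            f"expected vector of length {domain.encoded_dim}, got {v.shape}"
        )
    x: dict[str, Any] = {}
    i = 0
    for name, lo, hi in domain.continuous:
        x[name] = lo + float(np.clip(v[i], 0.0, 1.0)) * (hi - lo)
        i += 1
    for name, levels in domain.categorical:
        block = v[i:i + len(levels)]
        x[name] = levels[int(np.argmax(block))]
        i += len(levels)
    return x


@dataclass(frozen=True)
class Observation:
    """One evaluated condition with its normalized-peak-area objective."""

    x: dict[str, Any]
    y: float
    acquisition: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise ValueError(f"objective must be finite, got {self.y}")


@dataclass
class OptimizerState:
    domain: DomainSpec
    history: list[Observation] = field(default_factory=list)
    acquisition_weights: dict[str, float] = field(
        default_factory=lambda: {a: 1.0 / len(ACQUISITIONS) for a in ACQUISITIONS}
    )
    rng_seed: int = 0
    n_asks: int = 0

    def design_matrix(self) -> np.ndarray:
        return np.array([encode(o.x, self.domain) for o in self.history])


class MixedBayesOptimizer:
    """Seeded ask-tell optimizer; see module docstring for the protocol.

    Parameters
    ----------
    n_init
        Number of space-filling (Latin hypercube) observations before the
        GP surrogate takes over.
    ucb_beta, ei_xi
        Exploration parameters of the UCB and EI acquisitions.
    weight_floor
        Renormalization floor: every acquisition retains at least
        ``weight_floor / n_acquisitions`` sampling probability.
    pool_size
        Candidate-pool size for acquisition maximization (random points
        plus local perturbations of the best observed conditions).
    """

    def __init__(
        self,
        domain: DomainSpec,
        seed: int = 0,
        n_init: int = 5,
        ucb_beta: float = 2.0,
        ei_xi: float = 0.01,
        weight_floor: float = 0.1,
        pool_size: int = 2000,
        weight_gain: float = 1.5,
    ) -> None:
        if pool_size < 1 or n_init < 1:
            raise ValueError("pool_size and n_init must be >= 1")
        self.state = OptimizerState(domain=domain, rng_seed=seed)
        self.n_init = n_init
        self.ucb_beta = ucb_beta
        self.ei_xi = ei_xi
        self.weight_floor = weight_floor
        self.pool_size = pool_size
        self.weight_gain = weight_gain
        self._rng = np.random.default_rng(seed)
        self.last_acquisitions: list[str | None] = []

    # ------------------------------------------------------------------ ask
    def ask(self, n: int = 1) -> list[dict[str, Any]]:
        """Propose ``n`` in-domain conditions to evaluate next.

        The acquisition that produced each proposal is exposed in
        ``self.last_acquisitions`` (``None`` for space-filling proposals) so
        that the caller can attribute outcomes when telling.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        proposals: list[dict[str, Any]] = []
        acqs: list[str | None] = []
        # space-filling until n_init observations exist (and at least two,
        # below which the surrogate is not fittable)
        in_init = len(self.state.history) < max(2, self.n_init)
        n_random = n if in_init else 0
        if n_random:
            proposals.extend(self._space_filling(n_random))
            acqs.extend([None] * n_random)
        if n - n_random > 0:
            gp = self._fit_surrogate()
            for _ in range(n - n_random):
                x, acq = self._propose_one(gp)
                proposals.append(x)
                acqs.append(acq)
        self.state.n_asks += n
        self.last_acquisitions = acqs
        return proposals

    def tell(self, observations: Sequence[Observation]) -> OptimizerState:
        """Record evaluated conditions and adapt acquisition weights."""
        for obs in observations:
            self.state.domain.validate(obs.x)
            if not math.isfinite(obs.y):
                raise ValueError("objective must be finite")
        for obs in observations:
            improved = (
                not self.state.history
                or obs.y > max(o.y for o in self.state.history)
            )
            if obs.acquisition in ACQUISITIONS and improved:
                self.state.acquisition_weights[obs.acquisition] *= self.weight_gain
            self.state.history.append(obs)
        self._renormalize_weights()
        return self.state

    def incumbent(self) -> Observation:
        """Best observation so far; earliest wins ties."""
        if not self.state.history:
            raise ValueError("no observations yet")
        return max(self.state.history, key=lambda o: o.y)  # stable: first max

    # --------------------------------------------------------------- internals
    def _renormalize_weights(self) -> None:
        w = self.state.acquisition_weights
        total = sum(w.values())
        n = len(ACQUISITIONS)
        floor = self.weight_floor / n
        scale = 1.0 - self.weight_floor
        self.state.acquisition_weights = {
            a: floor + scale * w[a] / total for a in ACQUISITIONS
        }

    def _space_filling(self, n: int) -> list[dict[str, Any]]:
        d = self.state.domain
        n_cont = len(d.continuous)
        if n_cont:
            sampler = qmc.LatinHypercube(
                d=n_cont, seed=self._rng.integers(2**31)
            )
            cont = sampler.random(n)
        else:
            cont = np.zeros((n, 0))
        out = []
        for row in cont:
            x: dict[str, Any] = {}
            for (name, lo, hi), u in zip(d.continuous, row):
                x[name] = lo + float(u) * (hi - lo)
            for name, levels in d.categorical:
                x[name] = levels[int(self._rng.integers(len(levels)))]
            out.append(x)
        return out

    def _fit_surrogate(self) -> GaussianProcessRegressor:
        X = self.state.design_matrix()
        y = np.array([o.y for o in self.state.history])
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(length_scale=0.5, length_scale_bounds=(1e-2, 1e2), nu=2.5)
            + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-10, 1e-1))
        )
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=0,
            random_state=int(self._rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            # hyperparameters pinned at a bound are acceptable for a
            # surrogate refit every iteration
            warnings.simplefilter("ignore")
            gp.fit(X, y)
        return gp

    def _candidate_pool(self) -> np.ndarray:
        """Random in-domain candidates plus perturbations of top conditions.

        Built directly in the encoded space: uniform draws on [0,1] for the
        scaled continuous block, uniform one-hot blocks for categoricals.
        """
        d = self.state.domain
        n_cont = len(d.continuous)
        rows = np.zeros((self.pool_size, d.encoded_dim))
        rows[:, :n_cont] = self._rng.random((self.pool_size, n_cont))
        col = n_cont
        for _, levels in d.categorical:
            hits = self._rng.integers(len(levels), size=self.pool_size)
            rows[np.arange(self.pool_size), col + hits] = 1.0
            col += len(levels)
        extra = []
        top = sorted(self.state.history, key=lambda o: -o.y)[:5]
        for obs in top:
            base = encode(obs.x, d)
            pert = np.tile(base, (20, 1))
            if n_cont:
                pert[:, :n_cont] = np.clip(
                    pert[:, :n_cont] + self._rng.normal(0, 0.05, (20, n_cont)),
                    0, 1,
                )
            extra.append(pert)
        return np.vstack([rows] + extra) if extra else rows

    def _uniform_random(self, n: int) -> list[dict[str, Any]]:
        d = self.state.domain
        out = []
        for _ in range(n):
            x: dict[str, Any] = {}
            for name, lo, hi in d.continuous:
                x[name] = lo + float(self._rng.random()) * (hi - lo)
            for name, levels in d.categorical:
                x[name] = levels[int(self._rng.integers(len(levels)))]
            out.append(x)
        return out

    def _propose_one(
        self, gp: GaussianProcessRegressor
    ) -> tuple[dict[str, Any], str]:
        acq = self._rng.choice(
            ACQUISITIONS,
            p=[self.state.acquisition_weights[a] for a in ACQUISITIONS],
        )
        pool = self._candidate_pool()
        mu, sd = gp.predict(pool, return_std=True)
        sd = np.maximum(sd, 1e-12)
        if acq == "ucb":
            score = mu + self.ucb_beta * sd
        elif acq == "ei":
            best = max(o.y for o in self.state.history)
            z = (mu - best - self.ei_xi) / sd
            score = (mu - best - self.ei_xi) * norm.cdf(z) + sd * norm.pdf(z)
        else:  # thompson: one joint posterior sample over the pool
            mu_c, cov = gp.predict(pool, return_cov=True)
            jitter = 1e-10 * np.trace(cov) / len(pool) + 1e-12
            L = np.linalg.cholesky(cov + jitter * np.eye(len(pool)))
            score = mu_c + L @ self._rng.standard_normal(len(pool))
        x = decode(pool[int(np.argmax(score))], self.state.domain)
        return x, str(acq)


def run_campaign(
    objective,
    domain: DomainSpec,
    budget: int,
    seed: int = 0,
    **optimizer_kwargs,
) -> tuple[MixedBayesOptimizer, list[Observation]]:
    """Sequential closed loop: ask one condition, evaluate, tell, repeat.

    ``objective`` maps a condition record to a finite scalar (larger is
    better).  Returns the optimizer and its full history.
    """
    opt = MixedBayesOptimizer(domain, seed=seed, **optimizer_kwargs)
    for _ in range(budget):
        (x,) = opt.ask(1)
        (acq,) = opt.last_acquisitions
        y = float(objective(x))
        opt.tell([Observation(x=x, y=y, acquisition=acq)])
    return opt, opt.state.history
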