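"""Closed-form oracles and summary statistics.

The oracles are the standard results the simulator must reproduce:

* :func:`expected_si_fixation_time` — mean time for a single product to
  percolate through a well-mixed SI population under pairwise transmission,
  ``sum_{k=1}^{N-1} 1 / (beta k (N-k)) = 2 H_{N-1} / (beta N)``.
* :func:`moran_fixation_probability` — fixation probability of a single
  mutant of selective advantage ``s`` in a Moran process,
  ``(1 - r^-1) / (1 - r^-N)`` with ``r = 1 + s`` (``1/N`` when neutral).
* :func:`sir_final_size` — largest root of the deterministic final-size
  relation ``z = 1 - exp(-R0 z)``.

The summary statistics operationalize the community-based vs
individual-based dichotomy: a population is *monomorphic* when every
entity holds exactly the same product set, and the polymorphism index is
the probability that two distinct entities differ.  The regime ratio
``T_fix * lambda_stim`` compares the mean fixation time of one product
with the innovation interarrival time: products fix faster than they
appear (community-based) when the ratio is small, and pile up concurrently
(individual-based) when it is large.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from math import exp, inf

from scipy.optimize import brentq

from .config import ModelConfig
from .events import Trajectory
from .state import PopulationState


def expected_si_fixation_time(N: int, beta: float) -> float:
    """Mean SI fixation time of one product seeded in one of N entities."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return sum(1.0 / (beta * k * (N - k)) for k in range(1, N))


def moran_fixation_probability(N: int, s: float) -> float:
    """Fixation probability of a single mutant with relative fitness 1 + s."""
    if N < 2:
        raise ValueError("N must be >= 2")
    r = 1.0 + s
    if r <= 0:
        raise ValueError("relative fitness 1 + s must be > 0")
    if r == 1.0:  # covers s = 0 and s below float resolution
        return 1.0 / N
    return (1.0 - 1.0 / r) / (1.0 - r ** (-N))


def sir_final_size(R0: float) -> float:
    """Largest root z of z = 1 - exp(-R0 z); 0 for subcritical R0 <= 1."""
    if R0 < 0:
        raise ValueError("R0 must be >= 0")
    if R0 <= 1.0:
        return 0.0
    f = lambda z: z - 1.0 + exp(-R0 * z)  # noqa: E731
    # f(0) = 0 is the trivial root; for R0 > 1, f < 0 just above 0 and
    # f(1) = exp(-R0) > 0, bracketing the epidemic root.
    return float(brentq(f, 1e-12, 1.0, xtol=1e-12, rtol=8.9e-16))


def polymorphism_index(state: PopulationState) -> float:
    """Probability two distinct alive entities hold unequal product sets."""
    alive = [e for e in state.entities if e.alive]
    n = len(alive)
    if n < 2:
        raise ValueError("polymorphism index needs at least 2 alive entities")
    counts = Counter(frozenset(e.products) for e in alive)
    same = sum(c * (c - 1) for c in counts.values())
    return 1.0 - same / (n * (n - 1))


def mean_fitness(state: PopulationState) -> float:
    """Mean of max(0, 1 + sum of effects) over alive entities; 0 on collapse."""
    alive = [e.id for e in state.entities if e.alive]
    if not alive:
        return 0.0
    return sum(state.fitness(i) for i in alive) / len(alive)


@dataclass(frozen=True)
class RegimeReport:
    """Classification of a run into the innovation-vs-fixation regimes."""

    expected_fixation_time: float
    innovation_interarrival: float
    regime_ratio: float
    classified_regime: str  # community_based | individual_based | marginal
    observed_monomorphic_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, *, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def regime_ratio(config: ModelConfig) -> tuple[float, float]:
    """(expected fixation time, T_fix * lambda_stim) for a config.

    With ``lambda_stim = 0`` the ratio is 0 (community-based by
    convention); with ``beta = 0`` products never fix, so the fixation
    time and the ratio are infinite.
    """
    if config.beta > 0:
        t_fix = expected_si_fixation_time(config.N, config.beta)
    else:
        t_fix = inf
    if config.lambda_stim == 0.0:
        return t_fix, 0.0
    return t_fix, t_fix * config.lambda_stim


def classify_regime(config: ModelConfig, trajectory: Trajectory) -> RegimeReport:
    """Compare the predicted regime ratio with the observed monomorphism."""
    if len(trajectory.samples) < 2:
        raise ValueError("regime classification needs at least 2 samples")
    t_fix, ratio = regime_ratio(config)
    if ratio < config.ratio_low:
        regime = "community_based"
    elif ratio > config.ratio_high:
        regime = "individual_based"
    else:
        regime = "marginal"
    interarrival = inf if config.lambda_stim == 0.0 else 1.0 / config.lambda_stim
    return RegimeReport(
        expected_fixation_time=t_fix,
        innovation_interarrival=interarrival,
        regime_ratio=ratio,
        classified_regime=regime,
        observed_monomorphic_fraction=trajectory.monomorphic_fraction,
    )
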