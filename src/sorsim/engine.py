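"""Exact stochastic event engine (Gillespie direct method).

Every enabled event instance carries an exponential clock; the engine
draws the waiting time to the next event from the aggregate rate

    Lambda = lambda_stim
           + beta  * sum_p holders(p) * eligible_non_holders(p)
           + gamma * #(entity, held product) pairs
           + delta * #(entity, held product) pairs
           + mu    * N_alive

then picks the event kind with probability proportional to its component
and delegates to the matching process module.  Populations here are
desk-scale, so the direct method (exact, no tau-leaping) is used
throughout; correctness over speed.

A single :class:`numpy.random.Generator` seeded from the config drives all
stochastic choices, so a run is fully reproducible: identical config and
seed give byte-identical event logs.
"""
from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

from . import analytics
from .config import ModelConfig
from .darwin import PopulationCollapse, apply_birth_death
from .events import EventRecord, Trajectory
from .processes import (
    ScheduledStimulus,
    apply_degradation,
    apply_recovery,
    apply_stimulus,
    apply_transmission,
)
from .state import PopulationState

_KINDS = ("stimulus", "transmission", "recovery", "degradation", "birth_death")
_APPLY = {
    "stimulus": apply_stimulus,
    "transmission": apply_transmission,
    "recovery": apply_recovery,
    "degradation": apply_degradation,
    "birth_death": apply_birth_death,
}

StopCondition = Callable[[PopulationState], bool]


def rate_components(
    state: PopulationState, config: ModelConfig
) -> tuple[float, float, float, float, float]:
    """Per-kind aggregate rates, computed from the state's incremental indices."""
    held = state.held_product_total()
    return (
        config.lambda_stim,
        config.beta * state.transmission_pair_sum(),
        config.gamma * held,
        config.delta * held,
        config.mu * state.n_alive,
    )


def total_rate(state: PopulationState, config: ModelConfig) -> float:
    """Aggregate event rate Lambda, recounted from scratch.

    This is the slow reference implementation used for validation; the
    engine itself uses the state's incrementally maintained sums (the two
    must always agree, which the test suite checks along trajectories).
    """
    for name in ("lambda_stim", "beta", "gamma", "delta", "mu"):
        if getattr(config, name) < 0:
            raise ValueError(f"negative rate parameter {name}")
    alive = [e for e in state.entities if e.alive]
    n = len(alive)
    holders: dict[int, int] = {}
    recovered: dict[int, int] = {}
    held = 0
    for e in alive:
        for pid in e.products:
            holders[pid] = holders.get(pid, 0) + 1
            held += 1
        for pid in e.recovered:
            recovered[pid] = recovered.get(pid, 0) + 1
    pair = sum(
        h * (n - h - recovered.get(pid, 0)) for pid, h in holders.items()
    )
    return (
        config.lambda_stim
        + config.beta * pair
        + (config.gamma + config.delta) * held
        + config.mu * n
    )


def _choose_and_apply(
    state: PopulationState,
    config: ModelConfig,
    rng: np.random.Generator,
    comps: Sequence[float],
    total: float,
) -> EventRecord:
    u = rng.random() * total
    acc = 0.0
    chosen = None
    for kind, r in zip(_KINDS, comps):
        if r <= 0.0:
            continue
        acc += r
        chosen = kind
        if u < acc:
            break
    assert chosen is not None
    return _APPLY[chosen](state, config, rng)


def gillespie_step(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> Optional[EventRecord]:
    """Advance the state by exactly one event.

    Returns the realized :class:`EventRecord`, or ``None`` if the total
    rate is zero (absorbing state; no step is taken and the clock does not
    advance).
    """
    comps = rate_components(state, config)
    total = sum(comps)
    if total <= 0.0:
        return None
    state.time += rng.exponential(1.0 / total)
    return _choose_and_apply(state, config, rng, comps, total)


def run(
    config: ModelConfig,
    stimulus_schedule: Optional[Sequence[ScheduledStimulus]] = None,
    stop_condition: Optional[StopCondition] = None,
    record_events: bool = True,
) -> Trajectory:
    """Simulate one trajectory until ``t_max``, absorption or collapse.

    Parameters
    ----------
    config
        Full model configuration, including the seed.
    stimulus_schedule
        Optional pre-drawn stimuli (time-sorted).  When given, the Poisson
        stimulus process is replaced by these deterministic arrivals —
        used to share one innovation stream between paired runs;
        ``lambda_stim`` must then be 0.
    stop_condition
        Optional predicate on the state, checked after every event; a
        truthy return ends the run early (e.g. fixation-or-loss detection).
    record_events
        Set False to skip storing the (possibly long) event log.

    A summary row is recorded at t = 0, every ``sample_dt`` thereafter,
    and at the final time reached.  Sample rows reflect the state as a
    right-continuous step function between events.
    """
    if stimulus_schedule is not None and config.lambda_stim != 0.0:
        raise ValueError("a stimulus schedule requires lambda_stim = 0")
    schedule = list(stimulus_schedule) if stimulus_schedule else []
    if any(schedule[i].time > schedule[i + 1].time for i in range(len(schedule) - 1)):
        raise ValueError("stimulus schedule must be time-sorted")

    rng = np.random.default_rng(config.seed)
    state = PopulationState.from_config(config)
    traj = Trajectory(config=config, final_state=state)

    sample_i = 0  # next sample index; sample times are sample_i * sample_dt

    def record(t: float) -> None:
        poly = analytics.polymorphism_index(state)
        n_alive = state.n_alive
        traj.samples.append(
            {
                "time": t,
                "mean_fitness": analytics.mean_fitness(state),
                "n_products_extant": state.extant_product_count(),
                "polymorphism_index": poly,
                "monomorphic": int(poly == 0.0),
                "n_entities": n_alive,
            }
        )

    record(0.0)
    sample_i = 1
    sched_i = 0
    t_max = config.t_max

    if stop_condition is not None and stop_condition(state):
        traj.stopped_early = True
        return traj

    while True:
        comps = rate_components(state, config)
        total = sum(comps)
        next_sched = schedule[sched_i].time if sched_i < len(schedule) else math.inf
        if total > 0.0:
            t_cand = state.time + rng.exponential(1.0 / total)
        else:
            t_cand = math.inf
        t_next = min(t_cand, next_sched)

        if math.isinf(t_next):
            # Nothing left that can happen: stop at the last event time.
            traj.absorbed = True
            break
        if t_next >= t_max:
            # Emit the remaining sample grid up to the horizon, then stop.
            while sample_i * config.sample_dt <= t_max * (1 + 1e-12):
                record(sample_i * config.sample_dt)
                sample_i += 1
            state.time = t_max
            break

        while sample_i * config.sample_dt < t_next:
            record(sample_i * config.sample_dt)
            sample_i += 1

        if next_sched <= t_cand:
            state.time = next_sched
            event = apply_stimulus(
                state, config, rng, forced=schedule[sched_i]
            )
            sched_i += 1
        else:
            state.time = t_cand
            try:
                event = _choose_and_apply(state, config, rng, comps, total)
            except PopulationCollapse:
                traj.collapsed = True
                break
        if record_events:
            traj.events.append(event)
        if stop_condition is not None and stop_condition(state):
            traj.stopped_early = True
            break

    last_t = traj.samples[-1]["time"]
    if state.time > last_t:
        record(state.time)
    return traj
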