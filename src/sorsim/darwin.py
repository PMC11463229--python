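"""Moran birth–death with fitness-proportional reproduction.

One birth–death event (total rate ``mu * N``) picks a parent with
probability proportional to fitness and a victim uniformly over all N
entities (the parent itself included — the standard Moran convention,
which makes the neutral fixation probability exactly 1/N).  The victim is
replaced by a copy of the parent in which each product is independently
retained with probability ``1 - epsilon`` (imperfect inheritance as
loss-at-birth; there is no spontaneous gain at birth — new products come
only from stimuli).  N is constant in all modes.

If every entity has fitness 0, no parent can reproduce and the population
has collapsed; the run terminates with a collapse flag.
"""
from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .events import EventRecord
from .state import PopulationState


class PopulationCollapse(RuntimeError):
    """All entities have zero fitness: nothing can reproduce."""


def apply_birth_death(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> EventRecord:
    """Execute one Moran birth–death event, mutating the state in place."""
    n = len(state.entities)
    fitness = [state.fitness(i) for i in range(n)]
    total_fitness = sum(fitness)
    if total_fitness <= 0.0:
        raise PopulationCollapse(
            f"all {n} entities have fitness 0 at t={state.time:.6g}"
        )

    u = rng.random() * total_fitness
    acc = 0.0
    parent_id = n - 1
    for i, w in enumerate(fitness):
        acc += w
        if u < acc:
            parent_id = i
            break
    victim_id = int(rng.integers(n))

    parent = state.entities[parent_id]
    # Snapshot before mutation: the victim may be the parent itself.
    parent_products = sorted(parent.products)
    parent_recovered = sorted(parent.recovered)
    if config.epsilon > 0.0:
        retained = [p for p in parent_products if rng.random() >= config.epsilon]
    else:
        retained = parent_products
    lost = tuple(p for p in parent_products if p not in set(retained))

    state.replace_entity(victim_id, retained, parent_recovered)
    return EventRecord(
        time=state.time,
        kind="birth_death",
        actor_primary=parent_id,
        actor_secondary=victim_id,
        products_lost=lost,
    )


def selection_differential(state: PopulationState) -> float:
    """Population variance in fitness across alive entities.

    Zero iff the population is fitness-monomorphic; a nonzero value is the
    raw material differential reproduction acts on.
    """
    fit = [state.fitness(e.id) for e in state.entities if e.alive]
    if len(fit) < 2:
        raise ValueError("selection differential needs at least 2 alive entities")
    m = sum(fit) / len(fit)
    return sum((w - m) ** 2 for w in fit) / len(fit)
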