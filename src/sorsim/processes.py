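"""Stimulus, transmission, recovery and degradation event generators.

These are the SOR/SI/SIR processes:

* **stimulus** — a population-level Poisson process (rate ``lambda_stim``)
  hits a uniformly chosen entity and triggers a new product whose effect
  class is drawn from ``(p_beneficial, p_neutral, p_deleterious)``.  In
  cumulative mode the new product extends the lineage tip and can only
  arise in an entity holding that tip (a stimulus with no eligible entity
  is a logged no-op).
* **transmission** — horizontal percolation: each ordered (holder,
  eligible non-holder) pair passes each product at rate ``beta``.
* **recovery** — SIR-style permanent immunity at per held-product rate
  ``gamma``; with ``gamma = 0`` the process is exactly SOR (SI, no loss).
* **degradation** — thermodynamic decay at per held-product rate
  ``delta``; unlike recovery, a degraded product can be re-acquired.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ModelConfig
from .events import EventRecord
from .state import PopulationState, ProductType


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus that actually created a product (not a no-op)."""

    time: float
    target_entity: int
    product_created: ProductType


@dataclass(frozen=True)
class ScheduledStimulus:
    """A pre-drawn stimulus used to share one innovation stream across runs."""

    time: float
    entity: int
    effect_class: str
    effect_size: float


def draw_effect(config: ModelConfig, rng: np.random.Generator) -> tuple[str, float]:
    """Sample an effect class and its signed size from the config mixture."""
    u = rng.random()
    if u < config.p_beneficial:
        return "beneficial", config.s_beneficial
    if u < config.p_beneficial + config.p_neutral:
        return "neutral", 0.0
    return "deleterious", -config.s_deleterious


def _lineage_tip(state: PopulationState) -> Optional[int]:
    return state.catalog[-1].id if state.catalog else None


def apply_stimulus(
    state: PopulationState,
    config: ModelConfig,
    rng: np.random.Generator,
    forced: Optional[ScheduledStimulus] = None,
) -> EventRecord:
    """Create a new product in one entity, or log a no-op.

    With ``forced`` set (shared-innovation-stream experiments) the target
    entity and effect are taken from the schedule rather than drawn; forced
    stimuli are only supported in independent (non-cumulative) mode.
    """
    if forced is not None:
        if config.cumulative:
            raise ValueError("scheduled stimuli require cumulative=False")
        product = state.create_product(
            forced.entity, forced.effect_class, forced.effect_size, parent_id=None
        )
        return EventRecord(
            time=state.time,
            kind="stimulus",
            actor_primary=forced.entity,
            product_id=product.id,
        )

    parent_id: Optional[int] = None
    if config.cumulative:
        tip = _lineage_tip(state)
        if tip is None:
            eligible = [e.id for e in state.entities if e.alive]
        else:
            eligible = sorted(
                eid for eid in state.holder_ids(tip) if state.entities[eid].alive
            )
            parent_id = tip
        if not eligible:
            # No entity holds the lineage tip: the stimulus cannot take;
            # logged (product_id None) so innovation opportunities stay
            # auditable.
            return EventRecord(time=state.time, kind="stimulus")
        target = eligible[int(rng.integers(len(eligible)))]
    else:
        alive = [e.id for e in state.entities if e.alive]
        target = alive[int(rng.integers(len(alive)))]

    effect_class, effect_size = draw_effect(config, rng)
    product = state.create_product(target, effect_class, effect_size, parent_id)
    return EventRecord(
        time=state.time,
        kind="stimulus",
        actor_primary=target,
        product_id=product.id,
    )


def apply_transmission(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> EventRecord:
    """One ordered (holder, eligible non-holder) pair transmits one product.

    The pair is uniform over all enabled pairs across products: a product
    is chosen with probability proportional to holders x eligible, then
    holder and recipient uniformly.  Entities in a product's recovered set
    are never eligible recipients.
    """
    total = state.transmission_pair_sum()
    if total <= 0:
        raise RuntimeError("transmission fired with no enabled pair")
    u = rng.random() * total
    acc = 0
    pid = -1
    for cand in state._transmissible:
        acc += state._weight(cand)
        if u < acc:
            pid = cand
            break
    if pid < 0:  # numerical edge: take the last transmissible product
        pid = cand  # type: ignore[possibly-undefined]

    holders = tuple(state._holders[pid])
    source = holders[int(rng.integers(len(holders)))]

    # Recipient: uniform over eligible entities, by rejection with a scan
    # fallback (rejection is fast except very near fixation).
    n = len(state.entities)
    recipient = -1
    for _ in range(8 * max(1, n // max(1, n - len(holders)))):
        cand_e = int(rng.integers(n))
        ent = state.entities[cand_e]
        if ent.alive and pid not in ent.products and pid not in ent.recovered:
            recipient = cand_e
            break
    if recipient < 0:
        eligible = [
            e.id
            for e in state.entities
            if e.alive and pid not in e.products and pid not in e.recovered
        ]
        recipient = eligible[int(rng.integers(len(eligible)))]

    state.add_product(recipient, pid)
    return EventRecord(
        time=state.time,
        kind="transmission",
        actor_primary=source,
        actor_secondary=recipient,
        product_id=pid,
    )


def _pick_held_pair(
    state: PopulationState, rng: np.random.Generator
) -> tuple[int, int]:
    """Uniformly choose one (entity, held product) pair; entity order by id."""
    total = state.held_product_total()
    if total <= 0:
        raise RuntimeError("no held product to pick")
    k = int(rng.integers(total))
    for entity in state.entities:
        m = len(entity.products)
        if k < m:
            pid = sorted(entity.products)[k]
            return entity.id, pid
        k -= m
    raise AssertionError("held-product index out of range")


def apply_recovery(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> EventRecord:
    """SIR recovery: a uniformly chosen held product becomes permanent immunity."""
    eid, pid = _pick_held_pair(state, rng)
    state.recover_product(eid, pid)
    return EventRecord(
        time=state.time, kind="recovery", actor_primary=eid, product_id=pid
    )


def apply_degradation(
    state: PopulationState, config: ModelConfig, rng: np.random.Generator
) -> EventRecord:
    """Degradation: a uniformly chosen held product is lost (re-acquirable)."""
    eid, pid = _pick_held_pair(state, rng)
    state.remove_product(eid, pid)
    return EventRecord(
        time=state.time, kind="degradation", actor_primary=eid, product_id=pid
    )
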