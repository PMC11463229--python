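"""Domain types: products, entities and the population state.

The population is a fixed, well-mixed collection of ``N`` entities.  An
entity is an abstracted autocatalytic-set holder: it carries a *set* of
product ids (presence/absence, no copy number) and, in SIR mode, a set of
product ids it has recovered from and can never re-acquire.  An entity's
fitness is additive with baseline 1 and floored at 0:

    fitness = max(0, 1 + sum of effect sizes over held products)

:class:`PopulationState` additionally maintains incremental bookkeeping
(holder sets per product, recovered counts, per-entity effect sums, the
transmission pair-sum) so the event engine runs in near-constant time per
event.  The bookkeeping is an implementation detail; the authoritative
state is ``entities`` + ``catalog``, and :meth:`check_consistency` verifies
the two agree.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .config import EFFECT_SIGN, ModelConfig

#: Baseline fitness of a product-free entity.
W0 = 1.0


@dataclass(frozen=True)
class ProductType:
    """An innovation ("product") that entities can hold and transmit.

    ``parent_id`` links products into a cumulative lineage (p -> p' -> p''):
    in cumulative mode a new product can only arise in an entity holding
    its parent.
    """

    id: int
    effect_class: str
    effect_size: float
    parent_id: Optional[int] = None
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError("product id must be >= 0")
        if self.effect_class not in EFFECT_SIGN:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        sign = EFFECT_SIGN[self.effect_class]
        if sign == 0:
            if self.effect_size != 0.0:
                raise ValueError("neutral product must have effect_size 0")
        elif self.effect_size * sign <= 0:
            raise ValueError(
                f"effect_size {self.effect_size} inconsistent with "
                f"class {self.effect_class!r}"
            )
        if self.parent_id is not None and self.parent_id >= self.id:
            raise ValueError("parent_id must be a smaller (earlier) product id")
        if self.origin_time < 0:
            raise ValueError("origin_time must be >= 0")


class Entity:
    """A population member: a bag of products plus SIR immunity bookkeeping."""

    __slots__ = ("id", "products", "recovered", "alive")

    def __init__(self, id: int):
        self.id = id
        self.products: set[int] = set()
        self.recovered: set[int] = set()
        self.alive = True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Entity(id={self.id}, products={sorted(self.products)}, "
            f"recovered={sorted(self.recovered)})"
        )


class PopulationState:
    """N entities, the product catalog and the simulation clock."""

    def __init__(self, n_entities: int):
        if n_entities < 2:
            raise ValueError("population needs at least 2 entities")
        self.time = 0.0
        self.entities = [Entity(i) for i in range(n_entities)]
        self.catalog: list[ProductType] = []
        self.next_product_id = 0
        # --- incremental indices -----------------------------------------
        self._holders: dict[int, set[int]] = {}
        self._recov_n: dict[int, int] = {}
        self._effect_sum = [0.0] * n_entities
        self._pair_sum = 0        # sum over products of holders * eligible
        self._held_total = 0      # sum over entities of len(products)
        self._extant = 0          # number of products with >= 1 holder
        self._transmissible: set[int] = set()  # products with pair weight > 0

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_config(cls, config: ModelConfig) -> "PopulationState":
        state = cls(config.N)
        for sp in config.init_products:
            size = config.seeded_effect_size(sp)
            state.create_product(0, sp.effect_class, size, parent_id=None)
            pid = state.next_product_id - 1
            for eid in range(1, sp.n_entities):
                state.add_product(eid, pid)
        return state

    # -- read access -------------------------------------------------------

    @property
    def n_alive(self) -> int:
        return sum(1 for e in self.entities if e.alive)

    def fitness(self, entity_id: int) -> float:
        return max(0.0, W0 + self._effect_sum[entity_id])

    def holder_count(self, product_id: int) -> int:
        return len(self._holders.get(product_id, ()))

    def holder_ids(self, product_id: int) -> frozenset[int]:
        return frozenset(self._holders.get(product_id, ()))

    def recovered_count(self, product_id: int) -> int:
        return self._recov_n.get(product_id, 0)

    def extant_product_count(self) -> int:
        """Number of catalog products currently held by at least one entity."""
        return self._extant

    def held_product_total(self) -> int:
        """Total (entity, held product) pairs — the gamma/delta event count."""
        return self._held_total

    def transmission_pair_sum(self) -> int:
        """Sum over products of holders x eligible non-holders."""
        return self._pair_sum

    # -- mutation ----------------------------------------------------------

    def _weight(self, pid: int) -> int:
        h = len(self._holders[pid])
        eligible = len(self.entities) - h - self._recov_n[pid]
        return h * eligible

    def _reweigh(self, pid: int, old_w: int) -> None:
        new_w = self._weight(pid)
        self._pair_sum += new_w - old_w
        if new_w > 0:
            self._transmissible.add(pid)
        else:
            self._transmissible.discard(pid)

    def create_product(
        self,
        entity_id: int,
        effect_class: str,
        effect_size: float,
        parent_id: Optional[int],
    ) -> ProductType:
        """Append a fresh product to the catalog and place it in one entity."""
        pid = self.next_product_id
        product = ProductType(
            id=pid,
            effect_class=effect_class,
            effect_size=effect_size,
            parent_id=parent_id,
            origin_time=self.time,
        )
        self.catalog.append(product)
        self.next_product_id += 1
        self._holders[pid] = set()
        self._recov_n[pid] = 0
        self.add_product(entity_id, pid)
        return product

    def add_product(self, entity_id: int, product_id: int) -> None:
        entity = self.entities[entity_id]
        if product_id in entity.products or product_id in entity.recovered:
            raise ValueError(
                f"entity {entity_id} cannot (re)acquire product {product_id}"
            )
        old_w = self._weight(product_id)
        entity.products.add(product_id)
        holders = self._holders[product_id]
        holders.add(entity_id)
        if len(holders) == 1:
            self._extant += 1
        self._effect_sum[entity_id] += self.catalog[product_id].effect_size
        self._held_total += 1
        self._reweigh(product_id, old_w)

    def remove_product(self, entity_id: int, product_id: int) -> None:
        entity = self.entities[entity_id]
        old_w = self._weight(product_id)
        entity.products.remove(product_id)
        holders = self._holders[product_id]
        holders.remove(entity_id)
        if not holders:
            self._extant -= 1
        self._effect_sum[entity_id] -= self.catalog[product_id].effect_size
        self._held_total -= 1
        self._reweigh(product_id, old_w)

    def recover_product(self, entity_id: int, product_id: int) -> None:
        """SIR recovery: the product is lost *and* can never be re-acquired."""
        self.remove_product(entity_id, product_id)
        old_w = self._weight(product_id)
        self.entities[entity_id].recovered.add(product_id)
        self._recov_n[product_id] += 1
        self._reweigh(product_id, old_w)

    def replace_entity(
        self,
        victim_id: int,
        new_products: Iterable[int],
        new_recovered: Iterable[int],
    ) -> None:
        """Moran replacement: the victim becomes a copy with the given sets.

        Callers must snapshot the parent's sets *before* calling, since the
        victim may be the parent itself.
        """
        victim = self.entities[victim_id]
        for pid in list(victim.products):
            self.remove_product(victim_id, pid)
        for pid in list(victim.recovered):
            old_w = self._weight(pid)
            victim.recovered.remove(pid)
            self._recov_n[pid] -= 1
            self._reweigh(pid, old_w)
        for pid in new_products:
            self.add_product(victim_id, pid)
        for pid in new_recovered:
            old_w = self._weight(pid)
            victim.recovered.add(pid)
            self._recov_n[pid] += 1
            self._reweigh(pid, old_w)

    # -- verification ------------------------------------------------------

    def check_consistency(self) -> None:
        """Assert the incremental indices match a from-scratch recount."""
        n = len(self.entities)
        holders: dict[int, set[int]] = {p.id: set() for p in self.catalog}
        recov: dict[int, int] = {p.id: 0 for p in self.catalog}
        effect = [0.0] * n
        held = 0
        for e in self.entities:
            if e.products & e.recovered:
                raise AssertionError("products and recovered sets overlap")
            for pid in e.products:
                holders[pid].add(e.id)
                effect[e.id] += self.catalog[pid].effect_size
                held += 1
            for pid in e.recovered:
                recov[pid] += 1
        pair = sum(
            len(h) * (n - len(h) - recov[pid]) for pid, h in holders.items()
        )
        extant = sum(1 for h in holders.values() if h)
        assert holders == self._holders, "holder index out of sync"
        assert recov == self._recov_n, "recovered index out of sync"
        assert held == self._held_total
        assert pair == self._pair_sum
        assert extant == self._extant
        for eid in range(n):
            assert abs(effect[eid] - self._effect_sum[eid]) < 1e-9
        transmissible = {
            pid for pid, h in holders.items()
            if len(h) * (n - len(h) - recov[pid]) > 0
        }
        assert transmissible == self._transmissible
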