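"""Event records and time-sampled trajectories, with CSV serialization.

Event log CSV columns: ``time, kind, actor_primary, actor_secondary,
product_id``.  For birth–death events the ``product_id`` column carries the
semicolon-joined ids of products lost in the imperfect copy.  A stimulus
row with an empty ``product_id`` is a logged no-op (cumulative mode with no
eligible entity).

Trajectory sample CSV columns: ``time, mean_fitness, n_products_extant,
polymorphism_index, monomorphic, n_entities``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig
    from .state import PopulationState

EVENT_KINDS = ("stimulus", "transmission", "recovery", "degradation", "birth_death")

EVENT_COLUMNS = ["time", "kind", "actor_primary", "actor_secondary", "product_id"]
SAMPLE_COLUMNS = [
    "time",
    "mean_fitness",
    "n_products_extant",
    "polymorphism_index",
    "monomorphic",
    "n_entities",
]


@dataclass(frozen=True)
class EventRecord:
    """One realized event of the exact stochastic simulation."""

    time: float
    kind: str
    actor_primary: Optional[int] = None
    actor_secondary: Optional[int] = None
    product_id: Optional[int] = None
    products_lost: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    def _product_field(self) -> str:
        if self.kind == "birth_death":
            return ";".join(str(p) for p in self.products_lost)
        return "" if self.product_id is None else str(self.product_id)


@dataclass
class Trajectory:
    """The full output of one run: samples, events and the final state."""

    config: "ModelConfig"
    samples: list[dict] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)
    final_state: "PopulationState" = None  # type: ignore[assignment]
    collapsed: bool = False
    absorbed: bool = False
    stopped_early: bool = False

    @property
    def samples_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=SAMPLE_COLUMNS)

    @property
    def events_df(self) -> pd.DataFrame:
        rows = [
            {
                "time": ev.time,
                "kind": ev.kind,
                "actor_primary": "" if ev.actor_primary is None else ev.actor_primary,
                "actor_secondary": ""
                if ev.actor_secondary is None
                else ev.actor_secondary,
                "product_id": ev._product_field(),
            }
            for ev in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def write_samples_csv(self, path: str | Path) -> None:
        self.samples_df.to_csv(path, index=False)

    def write_events_csv(self, path: str | Path) -> None:
        self.events_df.to_csv(path, index=False)

    def events_csv_bytes(self) -> bytes:
        return self.events_df.to_csv(index=False).encode()

    @property
    def final_mean_fitness(self) -> float:
        return self.samples[-1]["mean_fitness"] if self.samples else 0.0

    @property
    def monomorphic_fraction(self) -> float:
        """Fraction of sample rows in which all entities share one product set."""
        if not self.samples:
            return 0.0
        return sum(row["monomorphic"] for row in self.samples) / len(self.samples)
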