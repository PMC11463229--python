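"""Experiment configuration.

A single :class:`ModelConfig` specifies every rate, probability and mode
toggle of the simulator.  One corner of its parameter space —
``gamma = delta = mu = 0`` with ``p_beneficial = 1`` — is the baseline
self–other reorganization (SOR) model: a fixed population of identical
entities acquiring only-beneficial products through stimuli and horizontal
transmission, with no loss process of any kind.  Each nonzero rate switches
one ignored process back on:

``gamma``
    per held-product recovery rate; turns SOR (an SI process) into SIR.
``delta``
    per held-product degradation rate; products decay and may be re-caught.
``mu``
    Moran birth–death rate per entity; fitness-proportional reproduction
    with imperfect inheritance (per-product copy-loss probability
    ``epsilon``) — conventional Darwinian dynamics.
``p_neutral`` / ``p_deleterious``
    relax the only-beneficial-innovations assumption.

Configurations serialize to/from JSON with keys exactly equal to the field
names; unknown keys are rejected.
"""
from __future__ import annotations

import json
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

EffectClass = Literal["beneficial", "neutral", "deleterious"]

#: Sign each effect class must carry (0 means exactly zero).
EFFECT_SIGN = {"beneficial": 1, "neutral": 0, "deleterious": -1}


class SeededProduct(BaseModel):
    """A product already present at time zero, before any stimulus.

    The product is placed in entities ``0 .. n_entities-1`` (the population
    is well mixed, so the choice of which entities is immaterial).  When
    ``effect_size`` is omitted it defaults to the configured class
    magnitude (``+s_beneficial``, ``0`` or ``-s_deleterious``).
    """

    model_config = ConfigDict(extra="forbid")

    effect_class: EffectClass = "beneficial"
    n_entities: int = Field(default=1, ge=1)
    effect_size: Optional[float] = None

    @model_validator(mode="after")
    def _sign_consistent(self) -> "SeededProduct":
        if self.effect_size is not None:
            sign = EFFECT_SIGN[self.effect_class]
            if sign == 0 and self.effect_size != 0.0:
                raise ValueError("neutral seeded product must have effect_size 0")
            if sign != 0 and self.effect_size * sign <= 0 and self.effect_size != 0.0:
                raise ValueError(
                    f"effect_size {self.effect_size} contradicts class "
                    f"{self.effect_class!r}"
                )
        return self


class ModelConfig(BaseModel):
    """All rates, probabilities, mode toggles and the seed for one run.

    Rates are per unit simulation time.  ``lambda_stim`` is a
    population-level Poisson rate (stimuli hit a uniformly chosen entity);
    ``beta`` is per ordered (holder, eligible non-holder) pair per product;
    ``gamma`` and ``delta`` are per (entity, held product) pair; ``mu`` is
    per entity.
    """

    model_config = ConfigDict(extra="forbid")

    N: int = Field(default=100, ge=2, description="population size (constant)")
    lambda_stim: float = Field(default=0.01, ge=0.0)
    beta: float = Field(default=1.0, ge=0.0)
    gamma: float = Field(default=0.0, ge=0.0)
    delta: float = Field(default=0.0, ge=0.0)
    mu: float = Field(default=0.0, ge=0.0)
    epsilon: float = Field(default=0.0, ge=0.0, le=1.0)
    p_beneficial: float = Field(default=1.0, ge=0.0, le=1.0)
    p_neutral: float = Field(default=0.0, ge=0.0, le=1.0)
    p_deleterious: float = Field(default=0.0, ge=0.0, le=1.0)
    s_beneficial: float = Field(default=0.1, ge=0.0)
    s_deleterious: float = Field(default=0.1, ge=0.0)
    cumulative: bool = False
    t_max: float = Field(default=100.0, gt=0.0)
    sample_dt: float = Field(default=1.0, gt=0.0)
    seed: int = 0
    init_products: list[SeededProduct] = Field(default_factory=list)
    # Regime-classification thresholds on the ratio T_fix * lambda_stim.
    ratio_low: float = Field(default=0.1, gt=0.0)
    ratio_high: float = Field(default=10.0, gt=0.0)

    @model_validator(mode="after")
    def _cross_field(self) -> "ModelConfig":
        total = self.p_beneficial + self.p_neutral + self.p_deleterious
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                "p_beneficial + p_neutral + p_deleterious must equal 1 "
                f"(got {total!r})"
            )
        if self.ratio_low >= self.ratio_high:
            raise ValueError("ratio_low must be < ratio_high")
        for sp in self.init_products:
            if sp.n_entities > self.N:
                raise ValueError(
                    f"init_products: n_entities {sp.n_entities} exceeds N {self.N}"
                )
        return self

    # -- serialization -----------------------------------------------------

    def to_json(self, *, indent: int | None = 2) -> str:
        return self.model_dump_json(indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls.model_validate(json.loads(text))

    def is_baseline_sor(self) -> bool:
        """True in the loss-free, only-beneficial corner of parameter space."""
        return (
            self.gamma == 0.0
            and self.delta == 0.0
            and self.mu == 0.0
            and self.p_beneficial == 1.0
        )

    def seeded_effect_size(self, sp: SeededProduct) -> float:
        if sp.effect_size is not None:
            return sp.effect_size
        return {
            "beneficial": self.s_beneficial,
            "neutral": 0.0,
            "deleterious": -self.s_deleterious,
        }[sp.effect_class]
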