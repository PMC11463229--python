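"""Presets, replicate batches and validation — the experiment layer.

Each preset packages one qualitative demonstration as a one-command run:

``sor_baseline``
    the loss-free, only-beneficial corner: every innovation percolates to
    fixation, mean fitness is monotone non-decreasing and the population
    is monomorphic almost all the time.
``regime_map``
    the monomorphic/polymorphic dichotomy: the same SI process run with
    innovation pressure far below and far above the fixation rate.
``triple_lottery_relaxed``
    innovations drawn from a mixture in which random effects are mostly
    neutral or deleterious; with no selection the population drifts
    downhill in fitness.
``degradation_collapse``
    with product decay switched on and no new stimuli, the extant product
    count hits zero in every replicate.
``darwinian_takeover``
    paired runs sharing one innovation stream, with and without Moran
    selection; selection retains the beneficial innovations and purges the
    deleterious ones.
``multi_sir``
    a multi-infectious SIR: recurrent introductions, each spreading and
    burning out under recovery.

Replicate seeds derive as ``base_seed + replicate_index`` (simple,
documented, collision-free at desk scale).
"""
from __future__ import annotations

import json
import platform
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd
from pydantic import ValidationError

from . import analytics, engine
from .config import ModelConfig
from .events import Trajectory
from .processes import ScheduledStimulus


class ConfigError(ValueError):
    """Raised by :func:`validate_config`; carries one message per violation."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def validate_config(raw: Any) -> ModelConfig:
    """Parse a raw JSON string/dict into a fully defaulted, validated config.

    Every violated constraint produces one named error message, collected
    on the raised :class:`ConfigError`.
    """
    if isinstance(raw, (str, bytes)):
        try:
            raw = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ConfigError([f"invalid JSON: {exc}"]) from exc
    try:
        return ModelConfig.model_validate(raw)
    except ValidationError as exc:
        messages = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<config>"
            messages.append(f"{loc}: {err['msg']}")
        raise ConfigError(messages) from exc


# ---------------------------------------------------------------------------
# Replicate drivers
# ---------------------------------------------------------------------------


def run_replicates(
    config: ModelConfig,
    n_replicates: int,
    base_seed: Optional[int] = None,
    record_events: bool = False,
    stop_condition=None,
) -> list[Trajectory]:
    """Run ``n_replicates`` independent copies, seeds ``base_seed + i``."""
    base = config.seed if base_seed is None else base_seed
    out = []
    for i in range(n_replicates):
        cfg = config.model_copy(update={"seed": base + i})
        out.append(
            engine.run(cfg, stop_condition=stop_condition, record_events=record_events)
        )
    return out


def _single_product_config(
    N: int,
    effect_class: str = "neutral",
    effect_size: Optional[float] = None,
    **overrides: Any,
) -> ModelConfig:
    """A config with one product seeded in one entity and no stimuli."""
    init = [{"effect_class": effect_class, "n_entities": 1}]
    if effect_size is not None:
        init[0]["effect_size"] = effect_size
    base = dict(
        N=N,
        lambda_stim=0.0,
        beta=0.0,
        gamma=0.0,
        delta=0.0,
        mu=0.0,
        p_beneficial=1.0,
        p_neutral=0.0,
        p_deleterious=0.0,
        t_max=1e9,
        sample_dt=1e9,
        init_products=init,
    )
    base.update(overrides)
    return ModelConfig.model_validate(base)


def si_fixation_times(
    N: int, beta: float, n_replicates: int, seed: int
) -> np.ndarray:
    """Absorption (full-percolation) times of a single SI product."""
    config = _single_product_config(N, beta=beta)
    times = np.empty(n_replicates)
    for i, traj in enumerate(run_replicates(config, n_replicates, seed)):
        assert traj.absorbed and traj.final_state.holder_count(0) == N
        times[i] = traj.final_state.time
    return times


def moran_fixation_outcomes(
    N: int, s: float, n_replicates: int, seed: int, mu: float = 1.0
) -> np.ndarray:
    """Boolean fixation outcomes of one mutant product under Moran dynamics.

    The product has additive effect ``s`` (neutral when 0); no
    transmission, stimuli or loss processes — pure drift and selection.
    """
    if s > 0:
        cls, size = "beneficial", s
    elif s < 0:
        cls, size = "deleterious", s
    else:
        cls, size = "neutral", None
    config = _single_product_config(N, effect_class=cls, effect_size=size, mu=mu)

    def absorbed_state(state) -> bool:
        return state.holder_count(0) in (0, N)

    fixed = np.empty(n_replicates, dtype=bool)
    trajs = run_replicates(
        config, n_replicates, seed, stop_condition=absorbed_state
    )
    for i, traj in enumerate(trajs):
        h = traj.final_state.holder_count(0)
        assert h in (0, N), "run ended before absorption; raise t_max"
        fixed[i] = h == N
    return fixed


def sir_attack_fractions(
    N: int, R0: float, n_replicates: int, seed: int, gamma: float = 1.0
) -> np.ndarray:
    """Final attack fractions of a single-product stochastic SIR.

    One seeded infectious entity; pairwise transmission with
    ``beta = R0 * gamma / N`` so the basic reproduction number is ``R0``.
    The attack fraction is the fraction of entities that ever held the
    product (all of them end recovered).
    """
    beta = R0 * gamma / N
    config = _single_product_config(N, beta=beta, gamma=gamma)
    attacks = np.empty(n_replicates)
    for i, traj in enumerate(run_replicates(config, n_replicates, seed)):
        assert traj.absorbed
        attacks[i] = traj.final_state.recovered_count(0) / N
    return attacks


def major_outbreaks(attacks: np.ndarray, R0: float) -> np.ndarray:
    """Filter attack fractions to major outbreaks.

    A replicate counts as a major outbreak when its final size reaches at
    least 10% of the deterministic prediction — the documented exclusion
    rule for comparing against the large-N final-size root.
    """
    z = analytics.sir_final_size(R0)
    if z == 0.0:
        return attacks[:0]
    return attacks[attacks >= 0.1 * z]


def regime_monomorphic_fractions(
    N: int,
    beta: float,
    ratio: float,
    n_replicates: int,
    seed: int,
    n_innovations: float = 28.0,
    n_samples: int = 100,
) -> np.ndarray:
    """Per-replicate monomorphic time-fractions at a given regime ratio.

    ``lambda_stim`` is set so that ``T_fix * lambda_stim = ratio``; the
    horizon covers ``n_innovations`` expected innovations and the state is
    sampled at ``n_samples`` equally spaced times (the time-fraction
    estimate).  Baseline SOR corner (beneficial-only, loss-free).
    """
    t_fix = analytics.expected_si_fixation_time(N, beta)
    lam = ratio / t_fix
    t_max = n_innovations / lam
    config = ModelConfig(
        N=N,
        beta=beta,
        lambda_stim=lam,
        p_beneficial=1.0,
        t_max=t_max,
        sample_dt=t_max / n_samples,
    )
    fracs = np.empty(n_replicates)
    for i, traj in enumerate(run_replicates(config, n_replicates, seed)):
        fracs[i] = traj.monomorphic_fraction
    return fracs


def innovation_schedule(
    rng: np.random.Generator, config: ModelConfig, rate: float
) -> list[ScheduledStimulus]:
    """Pre-draw a Poisson stimulus stream (times, targets, effects)."""
    schedule = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= config.t_max:
            return schedule
        entity = int(rng.integers(config.N))
        u = rng.random()
        if u < config.p_beneficial:
            cls, size = "beneficial", config.s_beneficial
        elif u < config.p_beneficial + config.p_neutral:
            cls, size = "neutral", 0.0
        else:
            cls, size = "deleterious", -config.s_deleterious
        schedule.append(ScheduledStimulus(t, entity, cls, size))


def paired_selection_experiment(
    n_pairs: int,
    seed: int,
    N: int = 30,
    beta: float = 0.02,
    mu: float = 1.0,
    epsilon: float = 0.0,
    innovation_rate: float = 0.5,
    t_max: float = 60.0,
    p: tuple[float, float, float] = (0.25, 0.25, 0.5),
    s: float = 0.1,
) -> pd.DataFrame:
    """Head-to-head: Moran selection vs no selection on one innovation stream.

    For each pair, one stimulus schedule (times, target entities, effect
    draws) is generated, then two runs consume it: the selection arm with
    ``mu > 0`` and the drift arm with ``mu = 0``.  Everything else is
    identical except the engines' own event randomness.  Returns one row
    per pair with the final mean fitness of both arms.
    """
    base = dict(
        N=N,
        lambda_stim=0.0,
        beta=beta,
        p_beneficial=p[0],
        p_neutral=p[1],
        p_deleterious=p[2],
        s_beneficial=s,
        s_deleterious=s,
        epsilon=epsilon,
        t_max=t_max,
        sample_dt=t_max,
    )
    rows = []
    for i in range(n_pairs):
        stream_rng = np.random.default_rng(seed + i)
        template = ModelConfig.model_validate(dict(base, mu=0.0, seed=0))
        schedule = innovation_schedule(stream_rng, template, innovation_rate)
        cfg_sel = ModelConfig.model_validate(
            dict(base, mu=mu, seed=seed + 100_000 + i)
        )
        cfg_drift = ModelConfig.model_validate(
            dict(base, mu=0.0, seed=seed + 200_000 + i)
        )
        t_sel = engine.run(cfg_sel, stimulus_schedule=schedule, record_events=False)
        t_dft = engine.run(cfg_drift, stimulus_schedule=schedule, record_events=False)
        rows.append(
            {
                "pair": i,
                "n_innovations": len(schedule),
                "final_fitness_selection": analytics.mean_fitness(
                    t_sel.final_state
                ),
                "final_fitness_no_selection": analytics.mean_fitness(
                    t_dft.final_state
                ),
                "collapsed_selection": t_sel.collapsed,
            }
        )
    df = pd.DataFrame(rows)
    df["fitness_gain_of_selection"] = (
        df["final_fitness_selection"] - df["final_fitness_no_selection"]
    )
    return df


def degradation_lifetimes(
    delta: float, n_replicates: int, seed: int
) -> np.ndarray:
    """Loss times of one product held by one entity, no transmission."""
    config = _single_product_config(2, delta=delta)
    times = np.empty(n_replicates)
    for i, traj in enumerate(run_replicates(config, n_replicates, seed)):
        assert traj.absorbed and traj.final_state.extant_product_count() == 0
        times[i] = traj.final_state.time
    return times


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    description: str
    kind: str  # batch | paired | regime
    overrides: dict = field(default_factory=dict)
    replicates: int = 10


PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in [
        ExperimentPreset(
            name="sor_baseline",
            description=(
                "Loss-free, only-beneficial corner: monotone fitness, "
                "monomorphic end state."
            ),
            kind="batch",
            overrides=dict(
                N=50,
                beta=1.0,
                lambda_stim=0.005,
                p_beneficial=1.0,
                s_beneficial=0.1,
                t_max=1000.0,
                sample_dt=5.0,
            ),
            replicates=10,
        ),
        ExperimentPreset(
            name="regime_map",
            description=(
                "Monomorphic vs polymorphic regimes at regime ratios 0.01 "
                "and 100."
            ),
            kind="regime",
            overrides=dict(N=20, beta=1.0),
            replicates=100,
        ),
        ExperimentPreset(
            name="triple_lottery_relaxed",
            description=(
                "Mixed-effect innovations (25% beneficial, 25% neutral, 50% "
                "deleterious), no selection: fitness drifts below its start."
            ),
            kind="batch",
            overrides=dict(
                N=20,
                beta=1.0,
                lambda_stim=0.1,
                p_beneficial=0.25,
                p_neutral=0.25,
                p_deleterious=0.5,
                s_beneficial=0.1,
                s_deleterious=0.1,
                t_max=200.0,
                sample_dt=2.0,
            ),
            replicates=100,
        ),
        ExperimentPreset(
            name="degradation_collapse",
            description=(
                "Degradation on, stimuli off: every replicate loses all "
                "products."
            ),
            kind="batch",
            overrides=dict(
                N=10,
                beta=0.02,
                delta=0.2,
                lambda_stim=0.0,
                t_max=5000.0,
                sample_dt=50.0,
                init_products=[
                    {"effect_class": "beneficial", "n_entities": 3},
                    {"effect_class": "beneficial", "n_entities": 3},
                ],
            ),
            replicates=50,
        ),
        ExperimentPreset(
            name="darwinian_takeover",
            description=(
                "Paired runs on a shared innovation stream: Moran selection "
                "vs pure drift."
            ),
            kind="paired",
            overrides=dict(
                N=30,
                beta=0.02,
                mu=1.0,
                epsilon=0.0,
                lambda_stim=0.5,
                p_beneficial=0.25,
                p_neutral=0.25,
                p_deleterious=0.5,
                s_beneficial=0.1,
                s_deleterious=0.1,
                t_max=60.0,
            ),
            replicates=100,
        ),
        ExperimentPreset(
            name="multi_sir",
            description=(
                "Multi-infectious SIR: recurrent introductions, each burning "
                "out under recovery."
            ),
            kind="batch",
            overrides=dict(
                N=500,
                beta=0.004,
                gamma=1.0,
                lambda_stim=0.05,
                p_beneficial=0.0,
                p_neutral=1.0,
                p_deleterious=0.0,
                t_max=60.0,
                sample_dt=0.5,
                init_products=[{"effect_class": "neutral", "n_entities": 1}],
            ),
            replicates=10,
        ),
    ]
}

#: Regime ratios demonstrated by the ``regime_map`` preset.
REGIME_RATIOS = (0.01, 100.0)


def run_experiment(
    preset_name: str,
    overrides: Optional[dict] = None,
    out_dir: str | Path = "results",
    seed: Optional[int] = None,
    replicates: Optional[int] = None,
    quiet: bool = True,
    log: Callable[[str], None] = lambda msg: print(msg, file=sys.stderr),
) -> pd.DataFrame:
    """Run a preset's replicate batch and write its result files.

    Writes per-replicate trajectory CSVs, a pooled ``summary.csv``, the
    resolved ``config.json`` and a ``run_log.json`` with versions and
    seeds.  Returns the summary table.
    """
    if preset_name not in PRESETS:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    preset = PRESETS[preset_name]
    merged = dict(preset.overrides)
    merged.update(overrides or {})
    config = validate_config(merged)
    base_seed = config.seed if seed is None else seed
    n_rep = preset.replicates if replicates is None else replicates
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.perf_counter()
    if not quiet:
        log(f"[{preset_name}] {n_rep} replicates, base seed {base_seed}")

    if preset.kind == "paired":
        summary = paired_selection_experiment(
            n_pairs=n_rep,
            seed=base_seed,
            N=config.N,
            beta=config.beta,
            mu=config.mu,
            epsilon=config.epsilon,
            innovation_rate=config.lambda_stim,
            t_max=config.t_max,
            p=(config.p_beneficial, config.p_neutral, config.p_deleterious),
            s=config.s_beneficial,
        )
    elif preset.kind == "regime":
        rows = []
        for j, ratio in enumerate(REGIME_RATIOS):
            fracs = regime_monomorphic_fractions(
                config.N, config.beta, ratio, n_rep, base_seed + 1000 * j
            )
            t_fix = analytics.expected_si_fixation_time(config.N, config.beta)
            lam = ratio / t_fix
            regime = (
                "community_based"
                if ratio < config.ratio_low
                else "individual_based"
                if ratio > config.ratio_high
                else "marginal"
            )
            rows.append(
                {
                    "N": config.N,
                    "beta": config.beta,
                    "lambda_stim": lam,
                    "regime_ratio": ratio,
                    "monomorphic_fraction": float(np.mean(fracs)),
                    "classified_regime": regime,
                }
            )
            if not quiet:
                log(f"[{preset_name}] ratio {ratio}: {rows[-1]}")
        summary = pd.DataFrame(rows)
    else:
        rows = []
        for i, traj in enumerate(run_replicates(config, n_rep, base_seed,
                                                record_events=True)):
            traj.write_samples_csv(out / f"rep_{i:03d}_samples.csv")
            traj.write_events_csv(out / f"rep_{i:03d}_events.csv")
            final = traj.final_state
            rows.append(
                {
                    "replicate": i,
                    "seed": base_seed + i,
                    "final_time": final.time,
                    "final_mean_fitness": analytics.mean_fitness(final),
                    "final_n_products_extant": final.extant_product_count(),
                    "final_polymorphism_index": analytics.polymorphism_index(
                        final
                    ),
                    "monomorphic_fraction": traj.monomorphic_fraction,
                    "absorbed": traj.absorbed,
                    "collapsed": traj.collapsed,
                    "n_events": len(traj.events),
                }
            )
        summary = pd.DataFrame(rows)

    summary.to_csv(out / "summary.csv", index=False)
    (out / "config.json").write_text(config.to_json())
    run_log = {
        "preset": preset_name,
        "description": preset.description,
        "base_seed": base_seed,
        "replicates": n_rep,
        "replicate_seeds": f"{base_seed}..{base_seed + n_rep - 1}",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "elapsed_s": round(_time.perf_counter() - t0, 3),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    if not quiet:
        log(f"[{preset_name}] done in {run_log['elapsed_s']}s -> {out}")
    return summary
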