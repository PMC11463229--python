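"""Closed-form oracles and summary statistics.

The Moran oracle is cross-checked against an independent absorbing-chain
linear solve; the SI fixation-time and final-size oracles against direct
evaluation and bracketing properties.
"""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorsim import (
    ModelConfig,
    PopulationState,
    classify_regime,
    expected_si_fixation_time,
    mean_fitness,
    moran_fixation_probability,
    polymorphism_index,
    run,
    sir_final_size,
)


def moran_fixation_by_linear_solve(N: int, s: float) -> float:
    """Independent oracle: absorbing-chain solve of the Moran process.

    From i mutant copies, a birth-death event changes i by +1 with
    probability proportional to picking a mutant parent and a wild-type
    victim, by -1 symmetrically.  Fixation probabilities solve a linear
    system with absorbing states 0 and N.
    """
    r = 1.0 + s
    A = np.zeros((N + 1, N + 1))
    b = np.zeros(N + 1)
    A[0, 0] = 1.0
    A[N, N] = 1.0
    b[N] = 1.0
    for i in range(1, N):
        w = i * r + (N - i)
        up = (i * r / w) * ((N - i) / N)
        down = ((N - i) / w) * (i / N)
        stay = 1.0 - up - down
        A[i, i - 1] = down
        A[i, i] = stay - 1.0
        A[i, i + 1] = up
    # rows 1..N-1 encode phi_i = down*phi_{i-1} + stay*phi_i + up*phi_{i+1}
    return float(np.linalg.solve(A, b)[1])


class TestSiFixationTime:
    @pytest.mark.parametrize(
        "N,beta,expected",
        [
            (2, 1.0, 1.0),
            (3, 1.0, 1.0),
            (10, 0.5, 1.1315873015873015),
        ],
    )
    def test_closed_form_values(self, N, beta, expected):
        assert expected_si_fixation_time(N, beta) == pytest.approx(
            expected, rel=1e-12
        )

    def test_harmonic_number_identity(self):
        for N in (2, 5, 17, 40):
            harmonic = sum(1 / k for k in range(1, N))
            assert expected_si_fixation_time(N, 2.0) == pytest.approx(
                2 * harmonic / (2.0 * N)
            )

    @given(st.integers(3, 200), st.floats(0.01, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_beta_and_n(self, N, beta):
        assert expected_si_fixation_time(N, beta) > expected_si_fixation_time(
            N, beta * 1.5
        )
        assert expected_si_fixation_time(N + 1, beta) < expected_si_fixation_time(
            N, beta
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_si_fixation_time(20, 0.0)
        with pytest.raises(ValueError):
            expected_si_fixation_time(1, 1.0)


class TestMoranFixationProbability:
    def test_neutral_is_one_over_n(self):
        for N in (2, 10, 137):
            assert moran_fixation_probability(N, 0.0) == pytest.approx(1 / N)

    def test_hand_computed_values(self):
        assert moran_fixation_probability(2, 1.0) == pytest.approx(2 / 3)
        assert moran_fixation_probability(100, 0.1) == pytest.approx(
            0.09091568827, abs=1e-9
        )

    @pytest.mark.parametrize("N", [3, 10, 25, 50])
    @pytest.mark.parametrize("s", [-0.2, -0.05, 0.0, 0.05, 0.1, 1.0])
    def test_agrees_with_absorbing_chain_solve(self, N, s):
        assert moran_fixation_probability(N, s) == pytest.approx(
            moran_fixation_by_linear_solve(N, s), abs=1e-10
        )

    @given(st.floats(-0.5, 2.0), st.floats(0.001, 0.5))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_s(self, s, ds):
        assert moran_fixation_probability(20, s + ds) > moran_fixation_probability(
            20, s
        )

    def test_domain_error_for_nonpositive_relative_fitness(self):
        with pytest.raises(ValueError):
            moran_fixation_probability(10, -1.0)


class TestSirFinalSize:
    def test_subcritical_has_no_outbreak(self):
        assert sir_final_size(0.0) == 0.0
        assert sir_final_size(0.8) == 0.0
        assert sir_final_size(1.0) == 0.0

    def test_r0_two(self):
        z = sir_final_size(2.0)
        assert z == pytest.approx(0.79681213, abs=1e-7)
        assert z - 1 + math.exp(-2 * z) == pytest.approx(0.0, abs=1e-10)

    def test_large_r0_approaches_one(self):
        assert sir_final_size(20.0) > 0.999

    def test_continuous_and_increasing_above_threshold(self):
        grid = np.linspace(1.001, 8.0, 200)
        values = [sir_final_size(r) for r in grid]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[0] < 0.01  # continuity at the epidemic threshold


class TestPolymorphismIndex:
    def test_identical_entities_give_zero(self):
        state = PopulationState(6)
        assert polymorphism_index(state) == 0.0

    def test_all_distinct_give_one(self):
        state = PopulationState(4)
        for eid in range(1, 4):  # entity 0 empty, others distinct singletons
            state.create_product(eid, "beneficial", 0.1, parent_id=None)
        assert polymorphism_index(state) == 1.0

    def test_two_by_two_split(self):
        # genotypes {p} and {} split 2+2: discordant pairs / all = 2/3
        state = PopulationState(4)
        state.create_product(0, "beneficial", 0.1, parent_id=None)
        state.add_product(1, 0)
        assert polymorphism_index(state) == pytest.approx(2 / 3)

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_entity_relabeling(self, genotypes):
        def build(assignment):
            state = PopulationState(len(assignment))
            for g in range(4):
                state.create_product(0, "beneficial", 0.1, parent_id=None)
            for pid in range(4):  # detach the scaffold holder
                if pid in state.entities[0].products:
                    state.remove_product(0, pid)
            for eid, g in enumerate(assignment):
                for pid in range(g):
                    state.add_product(eid, pid)
            return state

        direct = polymorphism_index(build(genotypes))
        relabeled = polymorphism_index(build(list(reversed(genotypes))))
        assert direct == pytest.approx(relabeled)


class TestMeanFitness:
    def test_product_free_population(self):
        assert mean_fitness(PopulationState(5)) == 1.0

    def test_additive_effects(self):
        # entity 0 holds {+0.1, -0.05}, entity 1 empty -> (1.05 + 1)/2
        state = PopulationState(2)
        state.create_product(0, "beneficial", 0.1, parent_id=None)
        state.create_product(0, "deleterious", -0.05, parent_id=None)
        assert mean_fitness(state) == pytest.approx(1.025)

    def test_fitness_floor_at_zero(self):
        state = PopulationState(2)
        state.create_product(0, "deleterious", -1.5, parent_id=None)
        assert state.fitness(0) == 0.0
        assert mean_fitness(state) == pytest.approx(0.5)


class TestClassifyRegime:
    def _traj(self, cfg):
        return run(cfg)

    def test_no_stimuli_is_community_based_by_convention(self):
        cfg = ModelConfig(
            N=5, lambda_stim=0.0, beta=1.0, t_max=10.0, sample_dt=1.0,
            init_products=[{"n_entities": 1}],
        )
        report = classify_regime(cfg, self._traj(cfg))
        assert report.regime_ratio == 0.0
        assert report.classified_regime == "community_based"
        assert math.isinf(report.innovation_interarrival)

    def test_threshold_classification(self):
        t_fix = expected_si_fixation_time(20, 1.0)
        for lam, expected in [
            (0.01 / t_fix, "community_based"),
            (1.0 / t_fix, "marginal"),
            (100.0 / t_fix, "individual_based"),
        ]:
            cfg = ModelConfig(
                N=20, lambda_stim=lam, beta=1.0, t_max=5.0, sample_dt=1.0
            )
            report = classify_regime(cfg, self._traj(cfg))
            assert report.classified_regime == expected
            assert report.regime_ratio == pytest.approx(t_fix * lam)

    def test_report_serializes(self):
        cfg = ModelConfig(N=5, lambda_stim=0.1, beta=1.0, t_max=5.0, sample_dt=1.0)
        report = classify_regime(cfg, self._traj(cfg))
        assert "regime_ratio" in report.to_json()
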