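import pytest

from ontochron import (
    OnsetShift,
    SimulationConfig,
    TimeFrame,
    branch_and_bound_search,
    build_matrix_from_schedules,
    late_set,
    normalize_schedule,
    recovery_experiment,
    simulate_schedules,
)
from ontochron.synthetic import SimulationError

FRAME = TimeFrame((25, 50, 75))

# explicit onsets spread over development keep injected shifts predictable
EVEN_ONSETS = tuple((i + 1) * 100.0 / 11 for i in range(10))


class TestSimulateSchedules:
    def test_synchronic_species_share_onsets(self):
        # onsets are expressed in species-specific degree-days but
        # normalize back to one shared percent schedule
        schedules = simulate_schedules(SimulationConfig(n_species=3, seed=1))
        maps = [normalize_schedule(s) for s in schedules]
        for other in maps[1:]:
            assert set(other) == set(maps[0])
            for c, v in maps[0].items():
                assert other[c] == pytest.approx(v)

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=9, missing_rate=0.2)
        a = simulate_schedules(cfg)
        b = simulate_schedules(cfg)
        assert [(s.species, s.onsets, s.t100) for s in a] == [
            (s.species, s.onsets, s.t100) for s in b
        ]

    def test_shift_moves_exactly_the_named_onset(self):
        shift = OnsetShift("Species_1", [3], 20.0)
        cfg = SimulationConfig(
            n_species=2, n_characters=10, onset_percents=EVEN_ONSETS,
            heterochronies=(shift,), seed=5,
        )
        m1, m2 = (normalize_schedule(s) for s in simulate_schedules(cfg))
        assert m1[3] - m2[3] == pytest.approx(20.0)
        for c in set(m1) - {3}:
            assert m1[c] == pytest.approx(m2[c])

    def test_out_of_range_shift_rejected(self):
        cfg = SimulationConfig(
            n_species=2, n_characters=10, onset_percents=EVEN_ONSETS,
            heterochronies=(OnsetShift("Species_1", [10], 150.0),), seed=5,
        )
        with pytest.raises(SimulationError):
            simulate_schedules(cfg)

    def test_unknown_species_in_shift_rejected(self):
        cfg = SimulationConfig(
            n_species=2, n_characters=10, onset_percents=EVEN_ONSETS,
            heterochronies=(OnsetShift("Nessie", [1], 5.0),), seed=5,
        )
        with pytest.raises(SimulationError):
            simulate_schedules(cfg)

    def test_beyond_100_onset_absent_at_interior_landmarks(self):
        cfg = SimulationConfig(
            n_species=2, n_characters=10, onset_percents=EVEN_ONSETS,
            heterochronies=(OnsetShift("Species_1", [10], 60.0),), seed=5,
        )
        m = build_matrix_from_schedules(simulate_schedules(cfg), FRAME)
        # char 10 base onset ~90.9% + 60 -> beyond 100: never seen inside
        for lm in (25, 50, 75):
            assert m.row_of(f"Species_1_{lm}%")[9] == "0"


class TestRecovery:
    def test_synchronic_convention_is_perfect_scores(self):
        r = recovery_experiment(SimulationConfig(seed=2), FRAME)
        assert (r.precision, r.recall) == (1.0, 1.0)
        assert r.n_injected == r.n_reported == 0

    def test_two_species_delay_recovered(self):
        # one species delayed on one character across the 50% landmark
        shift = OnsetShift("Species_1", [5], 20.0)  # onset 45.5 -> 65.5
        cfg = SimulationConfig(
            n_species=2, n_characters=10, onset_percents=EVEN_ONSETS,
            heterochronies=(shift,), seed=4,
        )
        r = recovery_experiment(cfg, FRAME)
        assert r.recall == 1.0

    def test_noise_free_late_set_equals_injected_characters(self):
        chars = frozenset({4, 5})  # onsets 36.4 and 45.5 -> both cross 50
        cfg = SimulationConfig(
            n_species=4, n_characters=10, onset_percents=EVEN_ONSETS,
            heterochronies=(OnsetShift("Species_2", chars, 20.0),), seed=6,
        )
        m = build_matrix_from_schedules(simulate_schedules(cfg), FRAME)
        assert late_set(m, "Species_2", 50.0) == set(chars)
        r = recovery_experiment(cfg, FRAME)
        assert (r.precision, r.recall) == (1.0, 1.0)

    def test_synchronic_matrices_have_ci_one(self):
        for seed in range(5):
            schedules = simulate_schedules(SimulationConfig(seed=seed))
            m = build_matrix_from_schedules(schedules, FRAME)
            assert branch_and_bound_search(m).fit.ci == 1.0

    def test_recall_non_increasing_in_missing_rate(self):
        # grid of seeds x missing rates; mean strict recall must not rise.
        # Heavily masked matrices have huge plateaus of equally
        # parsimonious trees, so the tree stage runs in heuristic mode
        # (the scored detector is the set-based screen either way).
        from ontochron import SearchOptions

        opts = SearchOptions(mode="heuristic", max_trees=4)
        shift = OnsetShift("Species_1", [5], 20.0)
        rates = (0.0, 0.25, 0.5)
        means = []
        for rate in rates:
            recalls = []
            for seed in range(6):
                cfg = SimulationConfig(
                    n_species=4, n_characters=10, onset_percents=EVEN_ONSETS,
                    heterochronies=(shift,), missing_rate=rate, seed=seed,
                )
                recalls.append(recovery_experiment(cfg, FRAME, opts).recall)
            means.append(sum(recalls) / len(recalls))
        assert means[0] >= means[1] >= means[2]
        assert means[0] == 1.0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_species=0), dict(missing_rate=1.0), dict(missing_rate=-0.1)]
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            SimulationConfig(**kwargs)

    def test_onset_count_must_match(self):
        cfg = SimulationConfig(n_characters=5, onset_percents=(10.0, 20.0))
        with pytest.raises(SimulationError):
            simulate_schedules(cfg)
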