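"""Synthetic visit generator and the transition/survival/injection estimators,
validated by hand-counted examples and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from amdcea import (
    EstimationError,
    GeneratorConfig,
    default_natural_history_matrix,
    estimate_injection_rate,
    estimate_time_to_threshold,
    estimate_transition_matrix,
    generate_cohort,
    letters_to_state,
)
from amdcea.synthetic_emr import ETDRS_BAND_RANGES, read_visits, write_visits


def visits_from_states(states, eye_role="treated", patient_id=0, injected=None):
    n = len(states)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "eye_role": eye_role,
            "month_index": np.arange(n),
            "va_state": states,
            "letters": np.nan,
            "injected": injected if injected is not None else [False] * n,
        }
    )


@pytest.fixture(scope="module")
def base_generator(base_params):
    treated = base_params.monthly.probs
    return GeneratorConfig(
        n_patients=2000,
        treated_matrix=treated,
        fellow_matrix=default_natural_history_matrix(treated).probs,
        drop_median_months=6.0,
        injection_probability=0.3,
        seed=1,
    )


@pytest.fixture(scope="module")
def base_cohort(base_generator):
    return generate_cohort(base_generator)


class TestTransitionEstimator:
    def test_hand_counted_sequence(self):
        visits = visits_from_states([1, 1, 2, 1])
        with pytest.warns(UserWarning, match="identity row"):
            est, counts = estimate_transition_matrix(visits, "treated", 1)
        assert est.probs[0, 0] == pytest.approx(0.5)
        assert est.probs[0, 1] == pytest.approx(0.5)
        assert est.probs[1, 0] == pytest.approx(1.0)
        assert counts.sum() == 3

    def test_constant_state_gives_identity_row(self):
        visits = visits_from_states([3, 3, 3, 3])
        with pytest.warns(UserWarning):
            est, _ = estimate_transition_matrix(visits, "treated", 1)
        np.testing.assert_array_equal(est.probs[2], [0, 0, 1, 0, 0])

    def test_no_qualifying_pairs_raises(self):
        visits = visits_from_states([1, 2])
        with pytest.raises(EstimationError):
            estimate_transition_matrix(visits, "fellow", 1)
        with pytest.raises(EstimationError):
            estimate_transition_matrix(visits, "treated", 7)

    def test_cycle_spacing_respected(self):
        # months 0,2,4: no 1-month pairs, two 2-month pairs
        visits = visits_from_states([1, 2, 2])
        visits["month_index"] = [0, 2, 4]
        with pytest.raises(EstimationError):
            estimate_transition_matrix(visits, "treated", 1)
        with pytest.warns(UserWarning):
            est, counts = estimate_transition_matrix(visits, "treated", 2)
        assert counts.sum() == 2
        assert est.probs[0, 1] == 1.0


class TestGenerator:
    def test_identity_treated_matrix_constant_states(self, base_params):
        config = GeneratorConfig(
            n_patients=50,
            treated_matrix=np.eye(5),
            fellow_matrix=default_natural_history_matrix(base_params.monthly.probs).probs,
            seed=3,
        )
        visits = generate_cohort(config)
        treated = visits[visits["eye_role"] == "treated"]
        assert (treated["va_state"] == 1).all()

    def test_zero_injection_probability(self, base_params):
        config = GeneratorConfig(
            n_patients=50,
            treated_matrix=base_params.monthly.probs,
            fellow_matrix=default_natural_history_matrix(base_params.monthly.probs).probs,
            injection_probability=0.0,
            seed=3,
        )
        visits = generate_cohort(config)
        post = visits[(visits["eye_role"] == "treated") & (visits["month_index"] >= 3)]
        assert not post["injected"].any()
        assert estimate_injection_rate(visits) == 0.0

    def test_bitwise_reproducible(self, base_generator):
        a = generate_cohort(base_generator)
        b = generate_cohort(base_generator)
        pd.testing.assert_frame_equal(a, b)

    def test_fellow_eyes_never_injected(self, base_cohort):
        assert not base_cohort[base_cohort["eye_role"] == "fellow"]["injected"].any()

    def test_natural_history_matrix_is_worse(self, base_params):
        treated = base_params.monthly.probs
        nh = default_natural_history_matrix(treated).probs
        assert 1 - nh[0, 0] == pytest.approx(2 * (1 - treated[0, 0]), rel=1e-12)
        # worsening mass never decreases, improving mass never increases
        for i in range(5):
            assert nh[i, i + 1:].sum() >= treated[i, i + 1:].sum() - 1e-12
            assert nh[i, :i].sum() <= treated[i, :i].sum() + 1e-12

    def test_matrix_recovery_within_wilson_intervals(self, base_params, base_cohort):
        from statsmodels.stats.proportion import proportion_confint

        truth = base_params.monthly.probs
        est, counts = estimate_transition_matrix(base_cohort, "treated", 1)
        covered = total = 0
        for i in range(5):
            n_row = counts[i].sum()
            assert n_row > 0
            for j in range(5):
                lo, hi = proportion_confint(counts[i, j], n_row, method="wilson")
                covered += lo <= truth[i, j] <= hi
                total += 1
        assert covered / total >= 0.88  # a single 95% CI may miss

    def test_injection_rate_recovery(self, base_cohort):
        assert estimate_injection_rate(base_cohort) == pytest.approx(0.3, abs=0.02)


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # events at months 3 and 5, one censoring at 4 (n = 3)
        frames = [
            visits_from_states([1, 1, 1, 2], eye_role="fellow", patient_id=0),
            visits_from_states([1, 1, 1, 1, 1], eye_role="fellow", patient_id=1),
            visits_from_states([1, 1, 1, 1, 1, 3], eye_role="fellow", patient_id=2),
        ]
        visits = pd.concat(frames, ignore_index=True)
        curve = estimate_time_to_threshold(visits)
        assert curve.at(3) == pytest.approx(2 / 3)
        assert curve.at(5) == pytest.approx(0.0)
        assert curve.median == 5.0

    def test_all_censored_flat_survival(self):
        visits = pd.concat(
            [visits_from_states([1] * 6, eye_role="fellow", patient_id=i) for i in range(4)],
            ignore_index=True,
        )
        curve = estimate_time_to_threshold(visits)
        assert np.all(curve.survival == 1.0)
        assert curve.median == np.inf

    def test_no_fellow_records_raises(self):
        with pytest.raises(EstimationError):
            estimate_time_to_threshold(visits_from_states([1, 2], eye_role="treated"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_product_limit(self, seed):
        """On small cohorts the KM estimate equals the hand product-limit."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        frames = []
        durations, events = [], []
        for pid in range(n):
            d = int(rng.integers(1, 8))
            ev = bool(rng.random() < 0.7)
            states = [1] * d + ([2] if ev else [])
            if not ev:
                states = [1] * (d + 1)
            frames.append(visits_from_states(states, eye_role="fellow", patient_id=pid))
            durations.append(d if ev else len(states) - 1)
            events.append(ev)
        visits = pd.concat(frames, ignore_index=True)
        curve = estimate_time_to_threshold(visits)
        durations = np.array(durations)
        events = np.array(events)
        for t in np.unique(durations[events]):
            s = 1.0
            for u in sorted(np.unique(durations[events & (durations <= t)])):
                at_risk = np.sum(durations >= u)
                d_u = np.sum((durations == u) & events)
                s *= 1 - d_u / at_risk
            assert curve.at(t) == pytest.approx(s, abs=1e-12)

    def test_drop_time_median_recovery(self, base_params):
        config = GeneratorConfig(
            n_patients=2000,
            treated_matrix=base_params.monthly.probs,
            fellow_matrix=default_natural_history_matrix(base_params.monthly.probs).probs,
            months=60,
            drop_median_months=12.0,
            seed=4,
        )
        curve = estimate_time_to_threshold(generate_cohort(config))
        assert abs(curve.median - 12.0) <= 1.0


class TestInjectionRate:
    def test_hand_ratio(self):
        injected = [True] * 3 + [True, False, True, False, False, True, True, False, False, False]
        visits = visits_from_states([1] * 13, injected=injected)
        assert estimate_injection_rate(visits) == pytest.approx(0.4)

    def test_no_post_loading_visits_raises(self):
        visits = visits_from_states([1, 1], injected=[True, True])
        with pytest.raises(EstimationError):
            estimate_injection_rate(visits)


class TestLetters:
    def test_binning_at_cut_points(self):
        for band, (lo, hi) in ETDRS_BAND_RANGES.items():
            assert letters_to_state([lo, hi]).tolist() == [band, band]

    def test_generated_letters_bin_back_to_states(self, base_params):
        config = GeneratorConfig(
            n_patients=30,
            treated_matrix=base_params.monthly.probs,
            fellow_matrix=default_natural_history_matrix(base_params.monthly.probs).probs,
            include_letters=True,
            seed=2,
        )
        visits = generate_cohort(config)
        np.testing.assert_array_equal(
            letters_to_state(visits["letters"].to_numpy(dtype=int)),
            visits["va_state"].to_numpy(),
        )


class TestRoundTripCSV:
    def test_write_read_round_trip(self, tmp_path, base_params):
        config = GeneratorConfig(
            n_patients=10,
            treated_matrix=base_params.monthly.probs,
            fellow_matrix=default_natural_history_matrix(base_params.monthly.probs).probs,
            seed=0,
        )
        visits = generate_cohort(config)
        path = tmp_path / "visits.csv"
        write_visits(visits, path)
        back = read_visits(path)
        pd.testing.assert_frame_equal(
            back[["patient_id", "eye_role", "month_index", "va_state", "injected"]],
            visits[["patient_id", "eye_role", "month_index", "va_state", "injected"]],
        )
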