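import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acoustocc import (
    AggregationConfig,
    DynamicsParams,
    GOOD_CLASSIFIER,
    MillerParams,
    RateParams,
    RecordingSchedule,
    build_encounter_history,
    fit_miller_model,
    negative_log_likelihood,
    simulate_event_table,
    simulate_occupancy,
    site_history_likelihood,
    survey_observation_probability,
)

PARAMS = MillerParams(psi=0.6, gamma=0.25, epsilon=0.25, p10=0.1, p11=0.5, b=0.3)


def oracle_site_likelihood(codes, seasons, p: MillerParams) -> float:
    """Independent brute force: enumerate every latent occupancy
    sequence and accumulate its path probability."""
    n_seasons = max(seasons)
    total = 0.0
    for zs in itertools.product((0, 1), repeat=n_seasons):
        prob = p.psi if zs[0] else 1 - p.psi
        for s in range(1, n_seasons):
            if zs[s - 1]:
                prob *= (1 - p.epsilon) if zs[s] else p.epsilon
            else:
                prob *= p.gamma if zs[s] else 1 - p.gamma
        for code, season in zip(codes, seasons):
            if zs[season - 1]:
                prob *= [1 - p.p11, p.p11 * (1 - p.b), p.p11 * p.b][code]
            else:
                prob *= [1 - p.p10, p.p10, 0.0][code]
        total += prob
    return total


unit = st.floats(0.0, 1.0)


@settings(derandomize=True, max_examples=200)
@given(p10=unit, p11=unit, b=unit, occupied=st.booleans())
def test_observation_probabilities_normalize(p10, p11, b, occupied):
    params = MillerParams(0.5, 0.2, 0.2, p10, p11, b)
    probs = [
        survey_observation_probability(c, occupied, params) for c in (0, 1, 2)
    ]
    assert all(p >= 0 for p in probs)
    assert sum(probs) == pytest.approx(1.0, abs=1e-12)


def test_observation_probability_values():
    params = MillerParams(0.5, 0.2, 0.2, p10=0.1, p11=0.8, b=0.25)
    assert survey_observation_probability(2, False, params) == 0.0
    assert survey_observation_probability(0, True, params) == pytest.approx(0.2)
    assert survey_observation_probability(1, True, params) == pytest.approx(0.6)
    assert survey_observation_probability(2, True, params) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        survey_observation_probability(3, True, params)


def test_single_survey_site_likelihoods():
    assert site_history_likelihood([0], [1], PARAMS) == pytest.approx(
        (1 - 0.6) * 0.9 + 0.6 * 0.5
    )
    assert site_history_likelihood([2], [1], PARAMS) == pytest.approx(0.6 * 0.5 * 0.3)


def test_two_season_history_matches_frozen_oracle_value():
    """History 120|000: value computed once by latent-state enumeration."""
    value = site_history_likelihood([1, 2, 0, 0, 0, 0], [1, 1, 1, 2, 2, 2], PARAMS)
    assert value == pytest.approx(0.004347, abs=1e-15)


def test_impossible_history_has_zero_likelihood():
    params = MillerParams(0.5, 0.2, 0.2, p10=0.1, p11=0.5, b=0.0)
    assert site_history_likelihood([2], [1], params) == 0.0
    assert negative_log_likelihood(np.array([[2]]), params, seasons=[1]) == np.inf


def test_forward_recursion_agrees_with_enumeration_oracle():
    """Random small instances, including >2 seasons, match the
    brute-force enumeration to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(8):
        n_seasons = int(rng.integers(1, 4))
        per_season = int(rng.integers(1, 4))
        seasons = [s + 1 for s in range(n_seasons) for _ in range(per_season)]
        codes = rng.integers(0, 3, size=len(seasons)).tolist()
        params = MillerParams(*rng.uniform(0.05, 0.95, size=6))
        expected = oracle_site_likelihood(codes, seasons, params)
        assert site_history_likelihood(codes, seasons, params) == pytest.approx(
            expected, abs=1e-12
        )


def test_history_sample_space_sums_to_one():
    """exp(-NLL) over all 3^4 single-site histories (2 seasons x 2
    surveys) is a probability distribution."""
    seasons = [1, 1, 2, 2]
    total = 0.0
    for codes in itertools.product((0, 1, 2), repeat=4):
        nll = negative_log_likelihood(np.array([codes]), PARAMS, seasons=seasons)
        total += np.exp(-nll)
    assert total == pytest.approx(1.0, abs=1e-10)


def test_nll_is_sum_over_sites():
    codes = np.array([[0, 1, 0, 0], [1, 1, 0, 2]])
    seasons = [1, 1, 2, 2]
    joint = negative_log_likelihood(codes, PARAMS, seasons=seasons)
    parts = sum(
        -np.log(site_history_likelihood(row.tolist(), seasons, PARAMS))
        for row in codes
    )
    assert joint == pytest.approx(parts, rel=1e-12)


def test_logit_roundtrip_leaves_nll_unchanged():
    from scipy.special import expit, logit

    codes = np.array([[0, 1, 2, 0]])
    seasons = [1, 1, 2, 2]
    round_tripped = MillerParams.from_array(expit(logit(PARAMS.to_array())))
    assert negative_log_likelihood(codes, PARAMS, seasons=seasons) == pytest.approx(
        negative_log_likelihood(codes, round_tripped, seasons=seasons), rel=1e-9
    )


def test_truth_beats_perturbation_on_average():
    """NLL at the generating parameters is lower than at perturbed
    parameters, on average over simulated datasets."""
    rng = np.random.default_rng(7)
    truth = PARAMS
    perturbed = MillerParams(0.75, 0.1, 0.4, 0.25, 0.35, 0.5)
    wins = 0
    n_trials = 20
    for _ in range(n_trials):
        z = np.empty((60, 2), dtype=int)
        z[:, 0] = rng.random(60) < truth.psi
        p_second = np.where(z[:, 0] == 1, 1 - truth.epsilon, truth.gamma)
        z[:, 1] = rng.random(60) < p_second
        codes = np.empty((60, 6), dtype=int)
        seasons = np.repeat([1, 2], 3)
        for s in (1, 2):
            occ = z[:, s - 1][:, None].astype(bool)
            u = rng.random((60, 3))
            occ_codes = np.where(
                u < 1 - truth.p11, 0, np.where(u < 1 - truth.p11 * truth.b, 1, 2)
            )
            unocc_codes = (u < truth.p10).astype(int)
            codes[:, seasons == s] = np.where(occ, occ_codes, unocc_codes)
        diff = negative_log_likelihood(
            codes, truth, seasons=seasons
        ) - negative_log_likelihood(codes, perturbed, seasons=seasons)
        wins += diff < 0
    assert wins > n_trials * 0.8


def _simulated_history(n_sites, seed):
    rng = np.random.default_rng(seed)
    dyn = DynamicsParams(0.6, 0.25, 0.25)
    schedule = RecordingSchedule()
    occ = simulate_occupancy(dyn, n_sites, 2, rng)
    events = simulate_event_table(occ, schedule, RateParams(100.0), GOOD_CLASSIFIER, rng)
    cfg = AggregationConfig(aggregation_days=1, threshold=0.95, confirm_prop=0.05)
    return build_encounter_history(events, occ, schedule, cfg, rng), dyn


def test_mle_recovers_generating_parameters():
    """A 500-site dataset under the discriminative classifier yields
    estimates within 0.05 of the generating values."""
    eh, dyn = _simulated_history(500, seed=2024)
    init = MillerParams(dyn.psi, dyn.gamma, dyn.epsilon, 0.02, 0.6, 0.07)
    fit = fit_miller_model(eh, init=init)
    assert fit.converged
    assert fit.estimates.psi == pytest.approx(dyn.psi, abs=0.05)
    assert fit.estimates.gamma == pytest.approx(dyn.gamma, abs=0.05)
    assert fit.estimates.epsilon == pytest.approx(dyn.epsilon, abs=0.05)


def test_fit_is_deterministic():
    eh, dyn = _simulated_history(80, seed=11)
    init = MillerParams(dyn.psi, dyn.gamma, dyn.epsilon, 0.02, 0.6, 0.07)
    a = fit_miller_model(eh, init=init)
    b = fit_miller_model(eh, init=init)
    assert a.estimates == b.estimates and a.neg_log_lik == b.neg_log_lik


def test_all_zero_history_hits_occupancy_boundary():
    codes = np.zeros((40, 6), dtype=int)
    fit = fit_miller_model(codes, seasons=[1, 1, 1, 2, 2, 2])
    assert not fit.converged  # no information: degenerate input
    assert fit.boundary_flags["psi"] or fit.estimates.psi < 0.01
    assert np.isfinite(fit.neg_log_lik)
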