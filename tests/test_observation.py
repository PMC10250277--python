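import numpy as np
import pytest
from scipy.special import logsumexp

from planscope import (
    BeliefState,
    TERMINATE,
    available_actions,
    fit_strategy_weights,
    sample_ground_truth,
    simulate_trial,
    trial_log_likelihood,
)
from planscope.observation import action_log_prob, average_click_likelihood
from planscope.strategies import Strategy, Trial


def test_zero_weights_give_uniform_softmax(env3, bank3):
    b = BeliefState(env3)
    w = np.zeros(bank3.n_features)
    for a in available_actions(b):
        assert action_log_prob(w, 1.0, b, a, bank3) == pytest.approx(np.log(1 / 13))


def test_single_binary_feature_closed_form(env3, bank3):
    # weight 1 on the is_immediate indicator: 3 of 13 actions carry it
    b = BeliefState(env3)
    w = np.zeros(bank3.n_features)
    w[bank3.names.index("is_immediate")] = 1.0
    p1 = np.exp(action_log_prob(w, 1.0, b, 1, bank3))
    assert p1 == pytest.approx(np.e / (3 * np.e + 10))
    p0 = np.exp(action_log_prob(w, 1.0, b, 7, bank3))
    assert p0 == pytest.approx(1 / (3 * np.e + 10))


def test_low_temperature_concentrates_on_argmax(env3, bank3):
    b = BeliefState(env3)
    w = np.zeros(bank3.n_features)
    w[bank3.names.index("stop_planning")] = 1.0
    assert np.exp(action_log_prob(w, 1e-3, b, TERMINATE, bank3)) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        action_log_prob(w, 0.0, b, TERMINATE, bank3)


def test_trial_log_likelihood_shrinking_action_set(env3, bank3, rng):
    w = np.zeros(bank3.n_features)
    gt = sample_ground_truth(env3, rng)
    t0 = Trial(env_name=env3.name, ground_truth=gt, actions=(TERMINATE,),
               click_values=(), path=env3.paths[0])
    assert trial_log_likelihood(w, 1.0, t0, env3, bank3) == pytest.approx(np.log(1 / 13))
    t2 = Trial(env_name=env3.name, ground_truth=gt, actions=(1, 7, TERMINATE),
               click_values=(gt[1], gt[7]), path=env3.paths[0])
    expected = np.log(1 / 13) + np.log(1 / 12) + np.log(1 / 11)
    assert trial_log_likelihood(w, 1.0, t2, env3, bank3) == pytest.approx(expected)


def test_trial_log_likelihood_matches_bruteforce_oracle(env3, bank3, registry3, rng):
    # independent per-step recomputation of normalized propensities
    w = rng.normal(size=bank3.n_features)
    tau = 0.7
    trial = simulate_trial(registry3.get("best_first"), env3, rng)
    total = 0.0
    b = BeliefState(env3)
    for a in trial.actions:
        acts = available_actions(b)
        scores = np.array([w @ bank3.compute_features(b, c) for c in acts]) / tau
        total += scores[acts.index(a)] - logsumexp(scores)
        if a != TERMINATE:
            b = b.observe(a, trial.ground_truth[a])
    assert trial_log_likelihood(w, tau, trial, env3, bank3) == pytest.approx(total)


def test_per_step_probabilities_normalize(env3, bank3, rng):
    for _ in range(300):
        gt = sample_ground_truth(env3, rng)
        b = BeliefState(env3)
        for n in rng.permutation(env3.clickable)[: rng.integers(0, 12)]:
            b = b.observe(int(n), gt[int(n)])
        w = rng.normal(scale=2.0, size=bank3.n_features)
        tau = float(rng.uniform(0.1, 5.0))
        acts = available_actions(b)
        probs = [np.exp(action_log_prob(w, tau, b, a, bank3)) for a in acts]
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)


def test_click_order_matters_when_features_depend_on_belief(env3, bank3, rng):
    gt = sample_ground_truth(env3, np.random.default_rng(8))
    w = np.zeros(bank3.n_features)
    w[bank3.names.index("ancestor_observed")] = 2.0
    t_fwd = Trial(env_name=env3.name, ground_truth=gt, actions=(1, 4, TERMINATE),
                  click_values=(gt[1], gt[4]), path=env3.paths[0])
    t_rev = Trial(env_name=env3.name, ground_truth=gt, actions=(4, 1, TERMINATE),
                  click_values=(gt[4], gt[1]), path=env3.paths[0])
    l1 = trial_log_likelihood(w, 1.0, t_fwd, env3, bank3)
    l2 = trial_log_likelihood(w, 1.0, t_rev, env3, bank3)
    assert l1 != pytest.approx(l2)


def test_fit_recovers_known_softmax_policy(env3, bank3):
    # generative policy IS a softmax with known weights; the fitted model
    # must reproduce its action distributions (weights themselves are only
    # identified up to likelihood-equivalent directions)
    rng = np.random.default_rng(11)
    w_true = np.zeros(bank3.n_features)
    w_true[bank3.names.index("depth")] = 1.2
    w_true[bank3.names.index("stop_planning")] = 1.5
    w_true[bank3.names.index("fraction_explored_at_stop")] = 3.0

    def softmax_policy(b):
        acts = available_actions(b)
        s = bank3.feature_matrix(b, acts) @ w_true
        p = np.exp(s - logsumexp(s))
        return dict(zip(acts, p / p.sum()))

    strat = Strategy(id=0, name="known_softmax", type_label="misc",
                     policy=softmax_policy)
    w_hat = fit_strategy_weights(strat, env3, bank3, n_sim=2000, seed=2)
    # compare predicted distributions on beliefs the policy actually visits
    beliefs = []
    for k in range(20):
        tr = simulate_trial(strat, env3, np.random.default_rng(100 + k))
        beliefs.extend(tr.replay_beliefs(env3))
    for b in beliefs:
        acts = available_actions(b)
        X = bank3.feature_matrix(b, acts)
        p_true = np.exp(X @ w_true - logsumexp(X @ w_true))
        p_hat = np.exp(X @ w_hat - logsumexp(X @ w_hat))
        assert np.abs(p_true - p_hat).max() < 0.05


def test_fitted_no_planning_terminates_immediately(env3, bank3, obs3, registry3):
    b = BeliefState(env3)
    sid = registry3.get("no_planning").id
    p_term = np.exp(action_log_prob(obs3.weights[sid], 1.0, b, TERMINATE, bank3))
    assert p_term >= 0.95


def test_fitted_models_beat_uniform_baseline_held_out(env3, bank3, obs3, registry3):
    rng = np.random.default_rng(21)
    w0 = np.zeros(bank3.n_features)
    for s in registry3:
        if s.name == "random_search":
            continue  # the random strategy IS the uniform baseline
        held_out = [simulate_trial(s, env3, rng) for _ in range(20)]
        ll_fit = sum(obs3.trial_log_likelihood(s.id, 1.0, t) for t in held_out)
        ll_unif = sum(trial_log_likelihood(w0, 1.0, t, env3, bank3) for t in held_out)
        assert ll_fit > ll_unif, s.name


def test_average_click_likelihood(env3, bank3, obs3, registry3, rng):
    gt = sample_ground_truth(env3, rng)
    trials = [Trial(env_name=env3.name, ground_truth=gt, actions=(TERMINATE,),
                    click_values=(), path=env3.paths[0]) for _ in range(5)]
    rnd_id = registry3.get("random_search").id
    res = average_click_likelihood(obs3, trials, [rnd_id] * 5)
    assert res.arithmetic == pytest.approx(1 / 13, abs=0.02)
    # a near-deterministic predictor on its own data approaches 1
    np_id = registry3.get("no_planning").id
    res2 = average_click_likelihood(obs3, trials, [np_id] * 5)
    assert res2.arithmetic > 0.95
    # best-fitting strategy is at least as likely as the random strategy
    sim = [simulate_trial(registry3.get("breadth_first"), env3, rng) for _ in range(10)]
    best = max(average_click_likelihood(obs3, sim, [s.id] * 10).arithmetic
               for s in registry3)
    base = average_click_likelihood(obs3, sim, [rnd_id] * 10).arithmetic
    assert best >= base


def test_weights_roundtrip_guarded_by_manifest_hash(tmp_path, env3, obs3,
                                                    registry3, bank3):
    p = tmp_path / "weights.csv"
    obs3.save_weights(p)
    from planscope.observation import ObservationModel
    fresh = ObservationModel(env3, registry3, bank3).load_weights(p)
    np.testing.assert_allclose(fresh.weight_matrix(), obs3.weight_matrix())
    # corrupt the manifest hash: loading must refuse
    text = p.read_text().replace(bank3.manifest_hash(), "deadbeef0000")
    p.write_text(text)
    with pytest.raises(ValueError, match="manifest"):
        ObservationModel(env3, registry3, bank3).load_weights(p)


def test_participant_cache_matches_direct_loglik(env3, bank3, obs3, registry3, rng):
    trials = [simulate_trial(registry3.get("local_search"), env3, rng, t=t + 1)
              for t in range(4)]
    cache = obs3.participant_cache(trials)
    for tau in (0.5, 1.0, 2.3):
        lm = cache.loglik_matrix(tau)
        for ti, tr in enumerate(trials):
            for sid in (0, 5, 11):
                direct = obs3.trial_log_likelihood(sid, tau, tr)
                assert lm[ti, sid] == pytest.approx(direct)
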