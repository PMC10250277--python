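import numpy as np
import pandas as pd
import pytest

from planscope import (
    build_environment,
    cluster_strategies,
    default_feature_bank,
    default_registry,
    relative_influence,
    relative_scores,
    strategy_distance,
    strategy_performance,
    time_course,
)
from planscope.analysis import distance_matrix, influence_profiles, proportion_z_test
from planscope.features import CATEGORIES
from planscope.inference import ParticipantResult


@pytest.fixture(scope="module")
def dmat(obs3):
    return distance_matrix(obs3, n_mc=200, seed=5)


def test_distance_matrix_symmetric_zero_diagonal(dmat):
    d = dmat.values
    np.testing.assert_array_equal(d, d.T)
    np.testing.assert_array_equal(np.diag(d), 0.0)
    assert (d >= 0).all()


def test_distance_separates_extremes(obs3, registry3, dmat):
    far = dmat[registry3.get("no_planning").id, registry3.get("exhaustive_search").id]
    near = dmat[registry3.get("best_first").id,
                registry3.get("best_first_satisficing").id]
    assert far > 5 * near


def test_pairwise_distance_symmetry_and_self_zero(obs3):
    assert strategy_distance(obs3, 2, 2, n_mc=50, seed=1) == 0.0
    d12 = strategy_distance(obs3, 0, 3, n_mc=100, seed=1)
    d21 = strategy_distance(obs3, 3, 0, n_mc=100, seed=1)
    assert d12 == d21  # symmetric by construction
    assert d12 > 0


def test_clustering_trivial_cases(dmat):
    n = dmat.values.shape[0]
    every = cluster_strategies(dmat, n_clusters=n)
    assert len(set(every.labels.values())) == n
    one = cluster_strategies(dmat, n_clusters=1)
    assert len(set(one.labels.values())) == 1
    with pytest.raises(ValueError):
        cluster_strategies(np.array([[0, 1], [2, 0]]), 1)  # asymmetric


def test_clustering_recovers_planted_partition():
    # three well-separated groups with small within-group noise
    rng = np.random.default_rng(6)
    centers = np.array([0.0, 10.0, 25.0])
    pts = np.concatenate([c + 0.2 * rng.standard_normal(3) for c in centers])
    d = np.abs(pts[:, None] - pts[None, :])
    assign = cluster_strategies(d, n_clusters=3)
    groups = [{assign[i] for i in range(k, k + 3)} for k in (0, 3, 6)]
    assert all(len(g) == 1 for g in groups)
    assert len({next(iter(g)) for g in groups}) == 3


def test_relative_influence_hand_computed(bank3):
    # put signed category totals at (+2, -1, +1, 0, 0) -> RI (.5, .25, .25, 0, 0)
    w = np.zeros(bank3.n_features)

    def set_total(cat, total):
        idx = next(i for i, d in enumerate(bank3.definitions) if d.category == cat)
        w[idx] = total * bank3.definitions[idx].sign
    set_total("pavlovian", 2.0)
    set_total("model_free_values_heuristics", -1.0)
    set_total("model_based_metareasoning", 1.0)
    ri, degenerate = relative_influence(w, bank3)
    assert not degenerate
    assert ri["pavlovian"] == pytest.approx(0.5)
    assert ri["model_free_values_heuristics"] == pytest.approx(0.25)
    assert ri["model_based_metareasoning"] == pytest.approx(0.25)
    assert ri["mental_effort_avoidance"] == 0.0
    assert ri["satisficing_stopping"] == 0.0


def test_relative_influence_single_system_and_degenerate(bank3):
    w = np.zeros(bank3.n_features)
    idx = next(i for i, d in enumerate(bank3.definitions)
               if d.category == "mental_effort_avoidance")
    w[idx] = 3.0
    ri, _ = relative_influence(w, bank3)
    assert ri["mental_effort_avoidance"] == 1.0
    assert sum(ri.values()) == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        ri0, degenerate = relative_influence(np.zeros(bank3.n_features), bank3)
    assert degenerate and all(v == pytest.approx(0.2) for v in ri0.values())


def test_influence_profiles_normalized(obs3):
    prof = influence_profiles(obs3)
    assert list(prof.columns) == list(CATEGORIES)
    np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)
    assert (prof.values >= 0).all()


def _fake_result(seqs, names, types):
    parts = []
    for pid, s in seqs.items():
        parts.append(ParticipantResult(
            participant_id=pid, map_sequence=np.asarray(s), p_stay=0.5, tau=1.0,
            log_prob=0.0, strategy_names=[names[i] for i in s],
            type_labels=[types[i] for i in s]))
    return parts


def test_time_course_frequencies(registry3):
    names = [s.name for s in registry3]
    types = registry3.type_labels()
    single = _fake_result({"a": [2, 2, 2]}, names, types)
    tc = time_course(single, "strategy")
    assert (tc[names[2]] == 1.0).all()
    two = _fake_result({"a": [0, 0], "b": [1, 1]}, names, types)
    tc2 = time_course(two, "strategy")
    assert (tc2[names[0]] == 0.5).all() and (tc2[names[1]] == 0.5).all()
    np.testing.assert_allclose(tc2.sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        time_course([], "strategy")


def test_time_course_influence_level(obs3, rng):
    from planscope import GenerativeSequenceModel, StrategyInference, generate_participants
    ds, _ = generate_participants(GenerativeSequenceModel("random_per_trial"),
                                  obs3, n=2, T=4, seed=41)
    res = StrategyInference(obs3).infer_dataset(ds.participant_trials())
    infl = time_course(res, "influence")
    assert infl.shape == (4, 5)
    np.testing.assert_allclose(infl.sum(axis=1), 1.0, atol=1e-9)
    assert ((infl.values >= 0) & (infl.values <= 1)).all()


def test_strategy_performance_and_relative_scores(env3, registry3):
    # no clicks, greedy over all-unobserved paths -> zero-mean expectation
    score_np = strategy_performance(registry3.get("no_planning"), env3,
                                    n_sims=3000, seed=7)
    assert abs(score_np) < 3 * 60 / np.sqrt(3000)  # 3 MC SEs, path sd < 60
    scores = {0: score_np, 1: 25.0, 2: -10.0}
    rel = relative_scores(scores)
    assert rel[1] == 1.0 and rel[2] == 0.0 and 0 <= rel[0] <= 1
    with pytest.warns(UserWarning):
        flat = relative_scores({0: 5.0, 1: 5.0})
    assert flat == {0: 1.0, 1: 1.0}


def test_goal_setting_outperforms_myopic_in_increasing_variance(env3, registry3):
    # final-outcome rewards dwarf immediate ones, so prioritizing them pays
    goal = strategy_performance(registry3.get("goal_setting_backward"), env3,
                                n_sims=1500, seed=8)
    myopic = strategy_performance(registry3.get("myopic_all_immediate"), env3,
                                  n_sims=1500, seed=8)
    assert goal > myopic


def test_proportion_z_test_basic():
    z, p = proportion_z_test(90, 100, 50, 100)
    assert z > 0 and p < 0.001
    z0, p0 = proportion_z_test(50, 100, 50, 100)
    assert z0 == 0.0 and p0 == pytest.approx(1.0)
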