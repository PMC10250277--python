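"""Features describing a candidate planning operation in a belief state.

Each feature maps a ``(belief, action)`` pair — where the action is a click
on an uninspected node or TERMINATE — to a real number, and belongs to
exactly one of five decision-system categories:

- ``pavlovian``: attraction/repulsion based on observed rewards and losses
  that precede or follow the action's node on its path;
- ``model_free_values_heuristics``: structural and relational properties
  (depth, relatedness to already-observed nodes, explored-path membership);
- ``model_based_metareasoning``: how much the observation would reduce
  uncertainty about which plan is best (value of information);
- ``mental_effort_avoidance``: acting without further planning;
- ``satisficing_stopping``: conditions under which stopping rules would
  terminate planning (e.g. a path whose expected return reaches the
  aspiration level).

Click-specific features evaluate to 0 for TERMINATE and stopping features
evaluate to 0 for clicks, so all actions share one feature space. Each
feature carries a sign recording whether it represents an increase (+1)
or a decrease (-1) in its decision system, used by the relative-influence
decomposition. Values are raw (unstandardized); fitted weights are
interpretable only jointly with this manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np

from .environment import BeliefState, EnvironmentSpec
from .strategies import TERMINATE, available_actions

__all__ = [
    "CATEGORIES",
    "FeatureDefinition",
    "FeatureBank",
    "myopic_voi",
    "default_feature_bank",
]

CATEGORIES = (
    "pavlovian",
    "model_free_values_heuristics",
    "model_based_metareasoning",
    "mental_effort_avoidance",
    "satisficing_stopping",
)


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    category: str
    sign: int  # +1 increase in the decision system, -1 decrease
    evaluator: Callable[[BeliefState, int], float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


def myopic_voi(belief: BeliefState, node: int) -> float:
    """Expected improvement of the best path value from observing ``node``.

    The expectation runs over the node's reward distribution (exact for
    discrete rewards, Gauss-Hermite quadrature for normal ones). Always
    non-negative.
    """
    env = belief.env
    if belief.mask[node]:
        raise ValueError(f"node {node} is already observed")
    evs = belief.path_evs
    through = list(env.paths_through[node])
    others = [i for i in range(len(evs)) if i not in through]
    base_through = max(evs[i] for i in through) - belief.filled[node]
    m_other = max((evs[i] for i in others), default=-np.inf)
    points, weights = env.reward_models[int(env.depth[node])].quadrature()
    new_best = np.maximum(m_other, base_through + points)
    return float(max(np.dot(weights, new_best) - evs.max(), 0.0))


class FeatureBank:
    """Ordered feature registry with a shared-context fast evaluation path."""

    def __init__(self, env: EnvironmentSpec, definitions: Sequence[FeatureDefinition]):
        names = [d.name for d in definitions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        self.env = env
        self.definitions: List[FeatureDefinition] = list(definitions)
        self.names = names
        self.n_features = len(definitions)
        self.signs = np.array([d.sign for d in definitions], dtype=float)
        self.categories = [d.category for d in definitions]

    def category_map(self) -> Dict[str, str]:
        """Total mapping feature name -> decision-system category."""
        return {d.name: d.category for d in self.definitions}

    def compute_features(self, belief: BeliefState, action: int) -> np.ndarray:
        if action != TERMINATE and (action not in belief.env.clickable or belief.mask[action]):
            raise ValueError(f"action {action} not available in this belief state")
        return np.array([d.evaluator(belief, action) for d in self.definitions])

    def feature_matrix(self, belief: BeliefState, actions: Sequence[int] | None = None) -> np.ndarray:
        """(n_actions, n_features) matrix; rows follow ``actions`` order."""
        if actions is None:
            actions = available_actions(belief)
        return np.stack([self.compute_features(belief, a) for a in actions])

    def manifest(self) -> List[dict]:
        return [
            {"name": d.name, "category": d.category, "sign": d.sign}
            for d in self.definitions
        ]

    def manifest_hash(self) -> str:
        payload = json.dumps(self.manifest(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


# ----------------------------------------------------------------------
# built-in feature set
# ----------------------------------------------------------------------

def _click_only(fn):
    def ev(b: BeliefState, a: int) -> float:
        return 0.0 if a == TERMINATE else float(fn(b, a))
    return ev


def _term_only(fn):
    def ev(b: BeliefState, a: int) -> float:
        return float(fn(b)) if a == TERMINATE else 0.0
    return ev


def _observed_ancestor_values(b: BeliefState, a: int) -> List[float]:
    return [b.filled[n] for n in b.env.ancestors[a] if b.mask[n]]


def _observed_descendant_values(b: BeliefState, a: int) -> List[float]:
    return [b.filled[n] for n in b.env.descendants[a] if b.mask[n]]


def default_feature_bank(env: EnvironmentSpec) -> FeatureBank:
    thr = float(env.satisficing_threshold)
    goal = float(env.best_leaf_value)
    n_clickable = len(env.clickable)
    n_immediate = int((env.depth == 1).sum())
    n_leaves = len(env.leaves)

    defs = [
        # --- model-free values and heuristics (structural/relational) ---
        FeatureDefinition(
            "depth", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: b.env.depth[a])),
        FeatureDefinition(
            "is_immediate", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: b.env.depth[a] == 1)),
        FeatureDefinition(
            "is_final_outcome", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: b.env.depth[a] == b.env.max_depth)),
        FeatureDefinition(
            "parent_observed", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: int(b.env.parent[a]) != b.env.start
                        and b.mask[int(b.env.parent[a])])),
        FeatureDefinition(
            "ancestor_observed", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: any(b.mask[n] for n in b.env.ancestors[a]))),
        FeatureDefinition(
            "successor_observed", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: any(b.mask[n] for n in b.env.descendants[a]))),
        FeatureDefinition(
            "sibling_observed", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: any(b.mask[n] for n in b.env.siblings[a]))),
        FeatureDefinition(
            "path_observed_count", "model_free_values_heuristics", +1,
            _click_only(lambda b, a: max(
                int(b.mask[b.env.path_arrays[p]].sum())
                for p in b.env.paths_through[a]))),
        FeatureDefinition(
            "on_best_immediate_branch", "model_free_values_heuristics", +1,
            _click_only(_best_branch_ind)),
        # --- Pavlovian ---
        FeatureDefinition(
            "max_preceding_reward", "pavlovian", +1,
            _click_only(lambda b, a: max(_observed_ancestor_values(b, a), default=0.0))),
        FeatureDefinition(
            "max_following_reward", "pavlovian", +1,
            _click_only(lambda b, a: max(_observed_descendant_values(b, a), default=0.0))),
        FeatureDefinition(
            "loss_preceding", "pavlovian", -1,
            _click_only(lambda b, a: any(v < 0 for v in _observed_ancestor_values(b, a)))),
        FeatureDefinition(
            "loss_following", "pavlovian", -1,
            _click_only(lambda b, a: any(v < 0 for v in _observed_descendant_values(b, a)))),
        # --- model-based metareasoning ---
        FeatureDefinition(
            "myopic_voi", "model_based_metareasoning", +1,
            _click_only(lambda b, a: myopic_voi(b, a))),
        FeatureDefinition(
            "node_uncertainty", "model_based_metareasoning", +1,
            _click_only(lambda b, a: b.env.node_std[a])),
        FeatureDefinition(
            "uncertainty_on_best_path", "model_based_metareasoning", +1,
            _click_only(lambda b, a: b.env.node_std[a]
                        if b.best_path_index in b.env.paths_through[a] else 0.0)),
        # --- mental-effort avoidance ---
        FeatureDefinition(
            "stop_planning", "mental_effort_avoidance", +1,
            _term_only(lambda b: 1.0)),
        FeatureDefinition(
            "clicks_made_at_stop", "mental_effort_avoidance", +1,
            _term_only(lambda b: b.n_observed)),
        # --- satisficing and stopping criteria ---
        FeatureDefinition(
            "aspiration_met", "satisficing_stopping", +1,
            _term_only(lambda b: b.best_ev >= thr)),
        FeatureDefinition(
            "best_path_value_at_stop", "satisficing_stopping", +1,
            _term_only(lambda b: b.best_ev)),
        FeatureDefinition(
            "best_final_outcome_found", "satisficing_stopping", +1,
            _term_only(lambda b: any(
                b.mask[leaf] and b.filled[leaf] >= goal for leaf in env.leaves))),
        FeatureDefinition(
            "positive_immediate_found", "satisficing_stopping", +1,
            _term_only(lambda b: any(
                b.mask[n] and b.filled[n] > 0
                for n in env.clickable if env.depth[n] == 1))),
        FeatureDefinition(
            "positive_final_found", "satisficing_stopping", +1,
            _term_only(lambda b: any(
                b.mask[leaf] and b.filled[leaf] > 0 for leaf in env.leaves))),
        FeatureDefinition(
            "fraction_explored_at_stop", "satisficing_stopping", +1,
            _term_only(lambda b: b.n_observed / n_clickable)),
        FeatureDefinition(
            "immediate_fraction_at_stop", "satisficing_stopping", +1,
            _term_only(lambda b: sum(
                1 for n in env.clickable
                if env.depth[n] == 1 and b.mask[n]) / n_immediate)),
        FeatureDefinition(
            "final_fraction_at_stop", "satisficing_stopping", +1,
            _term_only(lambda b: sum(1 for leaf in env.leaves if b.mask[leaf]) / n_leaves)),
    ]
    return FeatureBank(env, defs)


def _best_branch_ind(b: BeliefState, a: int) -> float:
    """1 if the action's path passes through the best observed first move."""
    env = b.env
    immediates = [n for n in env.clickable if env.depth[n] == 1 and b.mask[n]]
    if not immediates:
        return 0.0
    best = max(b.filled[n] for n in immediates)
    branch = {n for n in immediates if b.filled[n] >= best - 1e-12}
    anc = set(env.ancestors[a]) | {a}
    return float(bool(anc & branch))
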