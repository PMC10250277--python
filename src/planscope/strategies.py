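"""Planning strategies as stochastic generative click-policies.

A strategy maps a belief state to a probability distribution over the
available planning operations: clicking any not-yet-inspected node, or
TERMINATE (stop gathering information and act). Strategies are stochastic
only in that they choose uniformly at random among all *functionally
equivalent* operations at the current step; which operations are
equivalent is what defines the strategy.

The built-in set covers the strategy families described in the literature
on this paradigm — no planning, random search, myopic inspection of
immediate outcomes (with and without satisficing), breadth-first,
satisficing depth-first, best-first variants, goal-setting variants
(frugal, satisficing, maximizing-with-backward-planning, exhaustive),
consecutive second maximum, local search, middle-out, and exhaustive
search. The registry accepts user-defined additions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .environment import (
    BeliefState,
    EnvironmentSpec,
    GroundTruth,
    apply_click,
    sample_ground_truth,
)

__all__ = [
    "TERMINATE",
    "Strategy",
    "StrategyRegistry",
    "Trial",
    "available_actions",
    "strategy_policy",
    "simulate_trial",
    "default_registry",
]

#: Sentinel action id for "stop clicking and act".
TERMINATE = -1

Policy = Callable[[BeliefState], Dict[int, float]]


def available_actions(belief: BeliefState) -> List[int]:
    """All unclicked non-start nodes plus TERMINATE (always last)."""
    acts = [n for n in belief.env.clickable if not belief.mask[n]]
    acts.append(TERMINATE)
    return acts


@dataclass
class Strategy:
    """A named stochastic click-policy."""

    id: int
    name: str
    type_label: str
    policy: Policy
    params: dict = field(default_factory=dict)

    def action_distribution(self, belief: BeliefState) -> Dict[int, float]:
        dist = self.policy(belief)
        total = sum(dist.values())
        if not dist or abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"policy of {self.name!r} returned an improper distribution")
        return dist


class StrategyRegistry:
    """Ordered collection of strategies; registry order defines the index space."""

    def __init__(self) -> None:
        self._by_id: Dict[int, Strategy] = {}
        self._by_name: Dict[str, Strategy] = {}

    def register(self, name: str, type_label: str, policy: Policy,
                 params: Optional[dict] = None) -> Strategy:
        if name in self._by_name:
            raise ValueError(f"strategy {name!r} already registered")
        sid = len(self._by_id)
        s = Strategy(id=sid, name=name, type_label=type_label,
                     policy=policy, params=params or {})
        self._by_id[sid] = s
        self._by_name[name] = s
        return s

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self.strategies)

    @property
    def strategies(self) -> List[Strategy]:
        return [self._by_id[i] for i in range(len(self._by_id))]

    @property
    def ids(self) -> List[int]:
        return list(range(len(self._by_id)))

    def get(self, key) -> Strategy:
        if isinstance(key, str):
            if key not in self._by_name:
                raise KeyError(f"unknown strategy name {key!r}")
            return self._by_name[key]
        if key not in self._by_id:
            raise KeyError(f"unknown strategy id {key!r}")
        return self._by_id[key]

    def type_labels(self) -> List[str]:
        return [s.type_label for s in self.strategies]

    def manifest(self) -> List[dict]:
        return [
            {"id": s.id, "name": s.name, "type_label": s.type_label,
             "parameters": s.params}
            for s in self.strategies
        ]


def strategy_policy(strategy: Strategy, belief: BeliefState) -> Dict[int, float]:
    """The strategy's action distribution at ``belief``."""
    return strategy.action_distribution(belief)


@dataclass
class Trial:
    """One simulated or recorded participant-trial."""

    env_name: str
    ground_truth: GroundTruth
    actions: Tuple[int, ...]            # clicks then TERMINATE
    click_values: Tuple[float, ...]     # revealed reward per click
    path: Tuple[int, ...]
    t: int = 0

    @property
    def clicks(self) -> Tuple[int, ...]:
        return self.actions[:-1]

    @property
    def n_clicks(self) -> int:
        return len(self.actions) - 1

    def validate(self, env: EnvironmentSpec) -> None:
        if not self.actions or self.actions[-1] != TERMINATE:
            raise ValueError("trial must end with TERMINATE")
        clicks = self.actions[:-1]
        if len(set(clicks)) != len(clicks):
            raise ValueError("trial contains a repeated click")
        for node, value in zip(clicks, self.click_values):
            if node == env.start or node < 0 or node >= env.n_nodes:
                raise ValueError(f"invalid click target {node}")
            if abs(self.ground_truth[node] - value) > 1e-9:
                raise ValueError(f"revealed value for node {node} does not match ground truth")
        if tuple(self.path) not in set(map(tuple, env.paths)):
            raise ValueError("chosen path is not a valid start-to-leaf path")

    def replay_beliefs(self, env: EnvironmentSpec) -> List[BeliefState]:
        """Belief state before each action (length == len(actions))."""
        beliefs = []
        b = BeliefState(env)
        for a in self.actions:
            beliefs.append(b)
            if a != TERMINATE:
                b = apply_click(b, a, self.ground_truth)
        return beliefs


def simulate_trial(strategy: Strategy, env: EnvironmentSpec, rng,
                   truth: Optional[GroundTruth] = None, t: int = 0) -> Trial:
    """Sample one trial by following the strategy's policy to termination.

    After TERMINATE the path is chosen greedily by expected value under the
    final belief, ties broken uniformly at random.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if truth is None:
        truth = sample_ground_truth(env, rng)
    belief = BeliefState(env)
    actions: List[int] = []
    values: List[float] = []
    while True:
        dist = strategy.action_distribution(belief)
        acts = list(dist.keys())
        probs = np.array([dist[a] for a in acts])
        a = int(acts[rng.choice(len(acts), p=probs)])
        actions.append(a)
        if a == TERMINATE:
            break
        values.append(truth[a])
        belief = apply_click(belief, a, truth)
    evs = belief.path_evs
    best = np.flatnonzero(evs >= evs.max() - 1e-12)
    path = env.paths[int(rng.choice(best))]
    return Trial(env_name=env.name, ground_truth=truth, actions=tuple(actions),
                 click_values=tuple(values), path=tuple(path), t=t)


# ----------------------------------------------------------------------
# built-in policies
# ----------------------------------------------------------------------

def _uniform(actions: Sequence[int]) -> Dict[int, float]:
    p = 1.0 / len(actions)
    return {int(a): p for a in actions}


def _unobserved_at_depth(b: BeliefState, d: int) -> List[int]:
    env = b.env
    return [n for n in env.clickable if env.depth[n] == d and not b.mask[n]]


def _frontier(b: BeliefState) -> List[int]:
    """Unobserved nodes whose parent is observed or is the start node."""
    env = b.env
    out = []
    for n in env.clickable:
        if b.mask[n]:
            continue
        p = int(env.parent[n])
        if p == env.start or b.mask[p]:
            out.append(n)
    return out


def _best_observed_path_value(b: BeliefState) -> float | None:
    """Max total of fully observed paths, or None if no path fully observed."""
    best = None
    for arr in b.env.path_arrays:
        if b.mask[arr].all():
            total = float(b.filled[arr].sum())
            best = total if best is None else max(best, total)
    return best


def _terminate() -> Dict[int, float]:
    return {TERMINATE: 1.0}


def _no_planning(b: BeliefState) -> Dict[int, float]:
    return _terminate()


def _random_search(b: BeliefState) -> Dict[int, float]:
    return _uniform(available_actions(b))


def _exhaustive(b: BeliefState) -> Dict[int, float]:
    rest = [n for n in b.env.clickable if not b.mask[n]]
    return _uniform(rest) if rest else _terminate()


def _myopic_all(b: BeliefState) -> Dict[int, float]:
    cand = _unobserved_at_depth(b, 1)
    return _uniform(cand) if cand else _terminate()


def _myopic_satisficing(b: BeliefState) -> Dict[int, float]:
    if any(b.filled[n] > 0 for n in b.env.clickable
           if b.env.depth[n] == 1 and b.mask[n]):
        return _terminate()
    cand = _unobserved_at_depth(b, 1)
    return _uniform(cand) if cand else _terminate()


def _breadth_first(b: BeliefState) -> Dict[int, float]:
    for d in range(1, b.env.max_depth + 1):
        cand = _unobserved_at_depth(b, d)
        if cand:
            return _uniform(cand)
    return _terminate()


def _satisficing_depth_first(b: BeliefState) -> Dict[int, float]:
    best = _best_observed_path_value(b)
    if best is not None and best > 0:
        return _terminate()
    frontier = _frontier(b)
    if not frontier:
        return _terminate()
    env = b.env
    # continue down the deepest partially explored branch
    dmax = max(env.depth[n] for n in frontier)
    return _uniform([n for n in frontier if env.depth[n] == dmax])


def _best_first(b: BeliefState, satisfice: bool, threshold: float) -> Dict[int, float]:
    if satisfice and b.best_ev >= threshold:
        return _terminate()
    frontier = _frontier(b)
    if not frontier:
        return _terminate()
    # expand frontier nodes on the most promising partial path
    evs = b.path_evs
    score = {n: max(evs[p] for p in b.env.paths_through[n]) for n in frontier}
    top = max(score.values())
    return _uniform([n for n in frontier if score[n] >= top - 1e-12])


def _best_first_after_sweep(b: BeliefState, threshold: float) -> Dict[int, float]:
    cand = _unobserved_at_depth(b, 1)
    if cand:
        return _uniform(cand)
    return _best_first(b, satisfice=True, threshold=threshold)


def _goal_setting_satisficing(b: BeliefState) -> Dict[int, float]:
    env = b.env
    goal = env.best_leaf_value
    if any(b.filled[leaf] >= goal for leaf in env.leaves if b.mask[leaf]):
        return _terminate()
    cand = [leaf for leaf in env.leaves if not b.mask[leaf]]
    return _uniform(cand) if cand else _terminate()


def _frugal_goal_setting(b: BeliefState) -> Dict[int, float]:
    env = b.env
    if any(b.filled[leaf] > 0 for leaf in env.leaves if b.mask[leaf]):
        return _terminate()
    cand = [leaf for leaf in env.leaves if not b.mask[leaf]]
    return _uniform(cand) if cand else _terminate()


def _goal_setting_backward(b: BeliefState) -> Dict[int, float]:
    env = b.env
    cand = [leaf for leaf in env.leaves if not b.mask[leaf]]
    if cand:
        return _uniform(cand)
    # all final outcomes known: inspect the path to the best one, then stop
    best_leaf = max(env.leaves, key=lambda n: b.filled[n])
    todo = [n for n in env.ancestors[best_leaf] if not b.mask[n]]
    return _uniform(todo) if todo else _terminate()


def _goal_setting_exhaustive(b: BeliefState) -> Dict[int, float]:
    env = b.env
    cand = [leaf for leaf in env.leaves if not b.mask[leaf]]
    if cand:
        return _uniform(cand)
    rest = [n for n in env.clickable if not b.mask[n]]
    return _uniform(rest) if rest else _terminate()


def _consecutive_second_maximum(b: BeliefState) -> Dict[int, float]:
    env = b.env
    model = env.reward_models[env.max_depth]
    if model.kind == "discrete":
        second = sorted(set(model.values))[-2]
    else:
        second = model.sd  # 1 sd plays the role of the second-best outcome
    n_good = sum(1 for leaf in env.leaves if b.mask[leaf] and b.filled[leaf] >= second)
    if n_good >= 2:
        return _terminate()
    cand = [leaf for leaf in env.leaves if not b.mask[leaf]]
    return _uniform(cand) if cand else _terminate()


def _local_search(b: BeliefState) -> Dict[int, float]:
    env = b.env
    if b.n_observed == 0:
        return _uniform(list(env.clickable))
    neigh = set()
    for n in b.observed:
        cands = [int(env.parent[n])] + list(env.children.get(n, ())) + list(env.siblings[n])
        neigh.update(c for c in cands if c != env.start and not b.mask[c])
    if not neigh:
        return _terminate()
    return _uniform(sorted(neigh))


def _middle_out(b: BeliefState) -> Dict[int, float]:
    env = b.env
    mid = (env.max_depth + 1) // 2
    order = sorted(range(1, env.max_depth + 1), key=lambda d: (abs(d - mid), d))
    for d in order:
        cand = _unobserved_at_depth(b, d)
        if cand:
            return _uniform(cand)
    return _terminate()


def default_registry(env: EnvironmentSpec) -> StrategyRegistry:
    """The built-in strategy set for ``env``; registry order is the index space."""
    thr = float(env.satisficing_threshold)
    reg = StrategyRegistry()
    reg.register("no_planning", "frugal_planning", _no_planning)
    reg.register("random_search", "miscellaneous", _random_search)
    reg.register("exhaustive_search", "miscellaneous", _exhaustive)
    reg.register("myopic_all_immediate", "myopic_planning", _myopic_all)
    reg.register("myopic_satisficing", "myopic_planning", _myopic_satisficing)
    reg.register("breadth_first", "myopic_planning", _breadth_first)
    reg.register("satisficing_depth_first", "local_search", _satisficing_depth_first)
    reg.register("best_first", "forward_planning",
                 lambda b: _best_first(b, satisfice=False, threshold=thr))
    reg.register("best_first_satisficing", "forward_planning",
                 lambda b, thr=thr: _best_first(b, satisfice=True, threshold=thr),
                 params={"threshold": thr})
    reg.register("best_first_after_sweep", "forward_planning",
                 lambda b, thr=thr: _best_first_after_sweep(b, thr),
                 params={"threshold": thr})
    reg.register("goal_setting_satisficing", "frugal_goal_setting",
                 _goal_setting_satisficing, params={"goal": env.best_leaf_value})
    reg.register("frugal_goal_setting", "frugal_goal_setting", _frugal_goal_setting)
    reg.register("goal_setting_backward", "maximizing_goal_setting",
                 _goal_setting_backward)
    reg.register("goal_setting_exhaustive", "maximizing_goal_setting",
                 _goal_setting_exhaustive)
    reg.register("consecutive_second_maximum", "maximizing_goal_setting",
                 _consecutive_second_maximum)
    reg.register("local_search", "local_search", _local_search)
    reg.register("middle_out", "miscellaneous", _middle_out)
    return reg
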