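"""Mouselab-MDP planning environments.

A planning environment is a rooted out-tree whose non-start nodes hide
stochastic rewards. Participants (or simulated strategies) reveal rewards
one node at a time by paying a click cost, then commit to a start-to-leaf
path. The set of rewards revealed so far is the *belief state*; it is the
sole input to strategy policies and to the observation-model features.

Rewards are assigned per depth: every node at depth ``d`` (steps from the
start node, which has depth 0) draws independently from that depth's
distribution, either a discrete uniform over a finite integer set or a
zero-mean normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "RewardModel",
    "EnvironmentSpec",
    "GroundTruth",
    "BeliefState",
    "InvalidEnvironmentError",
    "build_environment",
    "enumerate_paths",
    "sample_ground_truth",
    "apply_click",
    "expected_path_value",
    "trial_score",
    "PRESETS",
]


class InvalidEnvironmentError(ValueError):
    """Raised when an environment spec violates a structural invariant."""


# Gauss-Hermite rule used for expectations over normal rewards.
_GH_POINTS, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(15)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass(frozen=True)
class RewardModel:
    """Distribution of the concealed reward at one tree depth.

    kind
        ``"discrete"`` — uniform over ``values``; ``"normal"`` — N(0, sd).
    """

    kind: str
    values: Tuple[float, ...] = ()
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "normal"):
            raise InvalidEnvironmentError(f"unknown reward model kind {self.kind!r}")
        if self.kind == "discrete" and len(self.values) == 0:
            raise InvalidEnvironmentError("discrete reward model needs values")
        if self.kind == "normal" and self.sd <= 0:
            raise InvalidEnvironmentError("normal reward model needs sd > 0")

    @property
    def mean(self) -> float:
        if self.kind == "discrete":
            return float(np.mean(self.values))
        return 0.0

    @property
    def std(self) -> float:
        if self.kind == "discrete":
            return float(np.std(self.values))
        return float(self.sd)

    @property
    def support_max(self) -> float:
        """Largest realistically attainable reward (2 sd for normal models)."""
        if self.kind == "discrete":
            return float(max(self.values))
        return 2.0 * self.sd

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "discrete":
            return rng.choice(np.asarray(self.values, dtype=float), size=size)
        return rng.normal(0.0, self.sd, size=size)

    def quadrature(self) -> Tuple[np.ndarray, np.ndarray]:
        """(points, weights) for expectations over this distribution."""
        if self.kind == "discrete":
            vals = np.asarray(self.values, dtype=float)
            return vals, np.full(len(vals), 1.0 / len(vals))
        return self.sd * _GH_POINTS, _GH_WEIGHTS

    def to_dict(self) -> dict:
        if self.kind == "discrete":
            return {"kind": "discrete", "values": list(self.values)}
        return {"kind": "normal", "sd": self.sd}

    @staticmethod
    def from_dict(d: Mapping) -> "RewardModel":
        if d["kind"] == "discrete":
            return RewardModel("discrete", values=tuple(d["values"]))
        return RewardModel("normal", sd=float(d["sd"]))


@dataclass
class EnvironmentSpec:
    """A validated planning-task tree with per-depth reward models."""

    name: str
    children: Dict[int, Tuple[int, ...]]
    reward_models: Dict[int, RewardModel]
    click_cost: float = 1.0
    start: int = 0
    satisficing_threshold: float | None = None

    # derived structure, filled by __post_init__
    n_nodes: int = field(init=False)
    depth: np.ndarray = field(init=False, repr=False)
    parent: np.ndarray = field(init=False, repr=False)
    paths: List[Tuple[int, ...]] = field(init=False, repr=False)
    leaves: Tuple[int, ...] = field(init=False, repr=False)
    max_depth: int = field(init=False)

    def __post_init__(self) -> None:
        self._validate_and_derive()

    # ------------------------------------------------------------------
    def _validate_and_derive(self) -> None:
        if self.click_cost < 0:
            raise InvalidEnvironmentError("click_cost must be >= 0")
        if self.start != 0:
            raise InvalidEnvironmentError("start node must be 0")
        nodes = {self.start}
        for k, ch in self.children.items():
            nodes.add(k)
            nodes.update(ch)
        n = len(nodes)
        if nodes != set(range(n)):
            raise InvalidEnvironmentError("node ids must be contiguous 0..n-1")

        parent = np.full(n, -1, dtype=int)
        for k, ch in self.children.items():
            for c in ch:
                if c == self.start:
                    raise InvalidEnvironmentError("start node cannot be a child")
                if c == k:
                    raise InvalidEnvironmentError(f"node {c} is its own child (cycle)")
                if parent[c] != -1:
                    raise InvalidEnvironmentError(f"node {c} has two parents")
                parent[c] = k

        depth = np.full(n, -1, dtype=int)
        depth[self.start] = 0
        order = [self.start]
        frontier = [self.start]
        while frontier:
            nxt: List[int] = []
            for u in frontier:
                for c in self.children.get(u, ()):
                    depth[c] = depth[u] + 1
                    nxt.append(c)
                    order.append(c)
            frontier = nxt
        if len(order) != n or (depth < 0).any():
            orphans = [int(i) for i in np.where(depth < 0)[0]]
            raise InvalidEnvironmentError(f"orphan nodes unreachable from start: {orphans}")

        self.n_nodes = n
        self.depth = depth
        self.parent = parent
        self.max_depth = int(depth.max())
        for d in range(1, self.max_depth + 1):
            if d not in self.reward_models:
                raise InvalidEnvironmentError(f"missing reward model for depth {d}")

        # all start-to-leaf paths, lexicographic by node id
        paths: List[Tuple[int, ...]] = []

        def walk(u: int, acc: List[int]) -> None:
            ch = sorted(self.children.get(u, ()))
            if not ch:
                paths.append(tuple(acc))
                return
            for c in ch:
                walk(c, acc + [c])

        walk(self.start, [self.start])
        self.paths = paths
        self.leaves = tuple(sorted(p[-1] for p in paths))

        # cached arrays used heavily by features / policies
        self.node_mean = np.zeros(n)
        self.node_std = np.zeros(n)
        for i in range(1, n):
            m = self.reward_models[int(depth[i])]
            self.node_mean[i] = m.mean
            self.node_std[i] = m.std
        # paths as index arrays without the start node
        self.path_arrays = [np.asarray(p[1:], dtype=int) for p in paths]
        self.paths_through: List[Tuple[int, ...]] = [()] * n
        through: List[List[int]] = [[] for _ in range(n)]
        for pi, arr in enumerate(self.path_arrays):
            for node in arr:
                through[int(node)].append(pi)
        self.paths_through = [tuple(v) for v in through]
        self.ancestors: List[Tuple[int, ...]] = []
        for i in range(n):
            acc = []
            u = int(parent[i])
            while u > 0:
                acc.append(u)
                u = int(parent[u])
            self.ancestors.append(tuple(acc))
        self.descendants: List[Tuple[int, ...]] = [()] * n
        desc: List[List[int]] = [[] for _ in range(n)]
        for i in range(n - 1, 0, -1):
            p = int(parent[i])
            if p >= 0:
                desc[p].extend([i] + desc[i])
        self.descendants = [tuple(sorted(v)) for v in desc]
        self.siblings: List[Tuple[int, ...]] = []
        for i in range(n):
            if i == self.start or parent[i] < 0:
                self.siblings.append(())
            else:
                sibs = tuple(c for c in self.children[int(parent[i])] if c != i)
                self.siblings.append(sibs)
        self.clickable = tuple(i for i in range(n) if i != self.start)

        if self.satisficing_threshold is None:
            leaf_model = self.reward_models[self.max_depth]
            self.satisficing_threshold = leaf_model.support_max
        self.best_leaf_value = self.reward_models[self.max_depth].support_max

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "children": {str(k): list(v) for k, v in self.children.items()},
            "reward_models": {str(d): m.to_dict() for d, m in self.reward_models.items()},
            "click_cost": self.click_cost,
            "satisficing_threshold": self.satisficing_threshold,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "EnvironmentSpec":
        return EnvironmentSpec(
            name=d.get("name", "custom"),
            children={int(k): tuple(v) for k, v in d["children"].items()},
            reward_models={int(k): RewardModel.from_dict(v) for k, v in d["reward_models"].items()},
            click_cost=float(d.get("click_cost", 1.0)),
            satisficing_threshold=d.get("satisficing_threshold"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @staticmethod
    def from_yaml(path) -> "EnvironmentSpec":
        with open(path) as fh:
            return EnvironmentSpec.from_dict(yaml.safe_load(fh))


def _three_step_children() -> Dict[int, Tuple[int, ...]]:
    # 3 first moves, one forced second move each, binary final split:
    # 1 + 3 + 3 + 6 = 13 nodes, 6 start-to-leaf paths.
    return {
        0: (1, 2, 3),
        1: (4,), 2: (5,), 3: (6,),
        4: (7, 8), 5: (9, 10), 6: (11, 12),
    }


def _five_step_children() -> Dict[int, Tuple[int, ...]]:
    # same 3-branch trunk, binary splits at the final two steps
    ch: Dict[int, Tuple[int, ...]] = {0: (1, 2, 3)}
    nxt = 4
    for b in (1, 2, 3):           # depth 1 -> single depth-2 child
        ch[b] = (nxt,)
        nxt += 1
    d2 = list(range(4, 7))
    for b in d2:                   # depth 2 -> single depth-3 child
        ch[b] = (nxt,)
        nxt += 1
    d3 = list(range(7, 10))
    for b in d3:                   # depth 3 -> two depth-4 children
        ch[b] = (nxt, nxt + 1)
        nxt += 2
    d4 = list(range(10, 16))
    for b in d4:                   # depth 4 -> two depth-5 leaves
        ch[b] = (nxt, nxt + 1)
        nxt += 2
    return ch


def _discrete(*values: float) -> RewardModel:
    return RewardModel("discrete", values=tuple(values))


PRESETS: Dict[str, dict] = {
    "increasing_variance_3step": {
        "children": _three_step_children,
        "reward_models": {
            1: _discrete(-4, -2, 2, 4),
            2: _discrete(-8, -4, 4, 8),
            3: _discrete(-48, -24, 24, 48),
        },
        "satisficing_threshold": 48.0,
    },
    "decreasing_variance_3step": {
        "children": _three_step_children,
        "reward_models": {
            1: _discrete(-48, -24, 24, 48),
            2: _discrete(-8, -4, 4, 8),
            3: _discrete(-4, -2, 2, 4),
        },
        "satisficing_threshold": 48.0,
    },
    "constant_variance_3step": {
        "children": _three_step_children,
        "reward_models": {d: _discrete(-10, -5, 5, 10) for d in (1, 2, 3)},
        # +-48 does not exist here; aspire to the maximum path value
        "satisficing_threshold": 30.0,
    },
    "increasing_variance_5step": {
        "children": _five_step_children,
        "reward_models": {
            1: RewardModel("normal", sd=1.0),
            2: RewardModel("normal", sd=2.0),
            3: RewardModel("normal", sd=4.0),
            4: RewardModel("normal", sd=8.0),
            5: RewardModel("normal", sd=32.0),
        },
    },
}


def build_environment(preset, click_cost: float = 1.0) -> EnvironmentSpec:
    """Build a preset environment by name, or validate a custom spec dict."""
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise KeyError(
                f"unknown preset {preset!r}; valid presets: {sorted(PRESETS)}"
            )
        cfg = PRESETS[preset]
        return EnvironmentSpec(
            name=preset,
            children=cfg["children"](),
            reward_models=dict(cfg["reward_models"]),
            click_cost=click_cost,
            satisficing_threshold=cfg.get("satisficing_threshold"),
        )
    if isinstance(preset, Mapping):
        return EnvironmentSpec.from_dict(preset)
    raise TypeError("preset must be a name or a spec mapping")


@dataclass(frozen=True)
class GroundTruth:
    """Realized concealed rewards for one trial (non-start node -> reward)."""

    rewards: Mapping[int, float]

    def __getitem__(self, node: int) -> float:
        return self.rewards[node]


def sample_ground_truth(env: EnvironmentSpec, rng) -> GroundTruth:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rewards = {
        int(i): float(env.reward_models[int(env.depth[i])].sample(rng))
        for i in env.clickable
    }
    return GroundTruth(rewards=rewards)


class BeliefState:
    """Immutable record of the rewards revealed so far within a trial."""

    __slots__ = ("env", "observed", "mask", "filled", "_cache")

    def __init__(self, env: EnvironmentSpec, observed: Mapping[int, float] | None = None):
        self.env = env
        self.observed: Dict[int, float] = dict(observed or {})
        mask = np.zeros(env.n_nodes, dtype=bool)
        filled = env.node_mean.copy()
        for k, v in self.observed.items():
            if k == env.start or k < 0 or k >= env.n_nodes:
                raise ValueError(f"cannot observe node {k}")
            mask[k] = True
            filled[k] = v
        self.mask = mask
        self.filled = filled
        self._cache: Dict[str, object] = {}

    def is_observed(self, node: int) -> bool:
        return bool(self.mask[node])

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    def observe(self, node: int, value: float) -> "BeliefState":
        if node == self.env.start:
            raise ValueError("cannot click the start node")
        if self.mask[node]:
            raise ValueError(f"node {node} already observed")
        new = dict(self.observed)
        new[node] = float(value)
        return BeliefState(self.env, new)

    # ---- cached per-belief summaries shared by features & policies ----
    @property
    def path_evs(self) -> np.ndarray:
        """Expected value of every path; unobserved nodes contribute their mean."""
        ev = self._cache.get("path_evs")
        if ev is None:
            ev = np.array([self.filled[arr].sum() for arr in self.env.path_arrays])
            self._cache["path_evs"] = ev
        return ev

    @property
    def best_ev(self) -> float:
        return float(self.path_evs.max())

    @property
    def best_path_index(self) -> int:
        return int(np.argmax(self.path_evs))


def apply_click(belief: BeliefState, node: int, truth: GroundTruth) -> BeliefState:
    """Reveal ``node``'s true reward, returning the successor belief state."""
    if node == belief.env.start:
        raise ValueError("cannot click the start node")
    return belief.observe(node, truth[node])


def enumerate_paths(env: EnvironmentSpec) -> List[Tuple[int, ...]]:
    """All start-to-leaf paths in deterministic (lexicographic) order."""
    return list(env.paths)


def expected_path_value(belief: BeliefState, path: Sequence[int]) -> float:
    """Observed rewards on the path plus distribution means of unobserved ones."""
    return float(sum(belief.filled[n] for n in path if n != belief.env.start))


def trial_score(path: Sequence[int], truth: GroundTruth, n_clicks: int,
                env: EnvironmentSpec) -> float:
    """Sum of rewards along the chosen path minus the click fees paid."""
    total = sum(truth[n] for n in path if n != env.start)
    return float(total - env.click_cost * n_clicks)


def environment_to_json(env: EnvironmentSpec) -> str:
    return json.dumps(env.to_dict(), indent=2, sort_keys=True)
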