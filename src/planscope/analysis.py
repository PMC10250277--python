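"""Strategy-space structure and decision-system decomposition.

Provides: Monte-Carlo symmetrized Kullback-Leibler distances between
strategies' click-sequence distributions; Ward hierarchical clustering of
the distance matrix into strategy types; the relative-influence
decomposition of fitted weights over the five decision systems; per-trial
time-course summaries of inferred sequences; and simulation-based strategy
performance scores with min-max normalization (r^rel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, wilcoxon

from .environment import EnvironmentSpec
from .features import CATEGORIES, FeatureBank
from .observation import ObservationModel
from .strategies import Strategy, simulate_trial

__all__ = [
    "DistanceMatrix",
    "strategy_distance",
    "distance_matrix",
    "cluster_strategies",
    "StrategyTypeAssignment",
    "relative_influence",
    "influence_profiles",
    "time_course",
    "strategy_performance",
    "relative_scores",
    "proportion_z_test",
    "wilcoxon_signed_rank",
]


@dataclass
class DistanceMatrix:
    """Symmetrized-KL distance estimates between strategies."""

    values: np.ndarray
    n_mc: int
    seed: int
    se: Optional[np.ndarray] = None  # pooled MC standard error per entry
    clamped: int = 0  # negative MC KL estimates clamped to zero

    def __getitem__(self, idx):
        return self.values[idx]


def _mc_kl_terms(obs_model: ObservationModel, n_mc: int, tau: float,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray, int]:
    """KL[i||j] matrix (and its MC standard error) from n_mc trials per strategy."""
    S = obs_model.n_strategies
    kl = np.zeros((S, S))
    se = np.zeros((S, S))
    clamped = 0
    for i in obs_model.registry.ids:
        trials = [obs_model.sample_trial(i, tau, rng) for _ in range(n_mc)]
        ll = obs_model.participant_cache(trials).loglik_matrix(tau)  # (n_mc, S)
        diffs = ll[:, i][:, None] - ll  # log p_i(d) - log p_j(d), d ~ p_i
        est = diffs.mean(axis=0)
        se[i] = diffs.std(axis=0, ddof=1) / np.sqrt(n_mc)
        neg = est < 0
        clamped += int(neg.sum()) - int(neg[i])  # diagonal is exactly 0
        est[neg] = 0.0
        kl[i] = est
    return kl, se, clamped


def distance_matrix(obs_model: ObservationModel, n_mc: int = 500,
                    seed: int = 0, tau: float = 1.0) -> DistanceMatrix:
    """Full pairwise symmetrized-KL matrix via Monte-Carlo integration.

    Trials (ground truth + click sequence) are sampled jointly from each
    strategy's fitted observation model at τ and scored under every
    strategy. Δ is exactly symmetric and has an exactly zero diagonal;
    negative finite-sample KL estimates are clamped at zero (count kept).
    """
    rng = np.random.default_rng(seed)
    kl, se, clamped = _mc_kl_terms(obs_model, n_mc, tau, rng)
    delta = kl + kl.T
    np.fill_diagonal(delta, 0.0)
    pooled = np.sqrt(se ** 2 + se.T ** 2)
    np.fill_diagonal(pooled, 0.0)
    return DistanceMatrix(values=delta, n_mc=n_mc, seed=seed, se=pooled,
                          clamped=clamped)


def strategy_distance(obs_model: ObservationModel, s1: int, s2: int,
                      n_mc: int = 500, seed: int = 0, tau: float = 1.0) -> float:
    """Δ(s1, s2) = KL[p(d|s1)||p(d|s2)] + KL[p(d|s2)||p(d|s1)], MC estimate."""
    if s1 == s2:
        return 0.0  # antisymmetric terms cancel on the same samples
    total = 0.0
    for a, b in ((s1, s2), (s2, s1)):
        # seed per sampled strategy so the estimate is exactly symmetric
        # in the argument order
        rng = np.random.default_rng(np.random.SeedSequence((seed, a)))
        diffs = []
        for _ in range(n_mc):
            trial = obs_model.sample_trial(a, tau, rng)
            ll = obs_model.participant_cache([trial]).loglik_matrix(tau)[0]
            diffs.append(ll[a] - ll[b])
        total += max(float(np.mean(diffs)), 0.0)
    return total


@dataclass
class StrategyTypeAssignment:
    labels: Dict[int, str]
    linkage: np.ndarray
    n_clusters: int

    def __getitem__(self, sid: int) -> str:
        return self.labels[sid]


def cluster_strategies(distances: DistanceMatrix | np.ndarray,
                       n_clusters: int) -> StrategyTypeAssignment:
    """Ward agglomeration of the strategy distance matrix into types."""
    d = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not (1 <= n_clusters <= d.shape[0]):
        raise ValueError("n_clusters must lie in [1, n_strategies]")
    dd = d.copy()
    np.fill_diagonal(dd, 0.0)
    Z = linkage(squareform(dd, checks=False), method="ward")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = {i: f"type_{int(c)}" for i, c in enumerate(flat)}
    return StrategyTypeAssignment(labels=labels, linkage=Z, n_clusters=n_clusters)


# ----------------------------------------------------------------------
# decision-system relative influence
# ----------------------------------------------------------------------

def relative_influence(weights: np.ndarray, bank: FeatureBank
                       ) -> Tuple[Dict[str, float], bool]:
    """RI_ds = |w_ds| / Σ|w_ds'| with w_ds the signed sum of the system's weights.

    Returns (profile, degenerate_flag); an all-zero weight vector yields
    the uniform profile with the flag set.
    """
    w = np.asarray(weights, dtype=float)
    signed = w * bank.signs
    totals = {c: 0.0 for c in CATEGORIES}
    for value, cat in zip(signed, bank.categories):
        totals[cat] += value
    denom = sum(abs(v) for v in totals.values())
    if denom == 0.0:
        warnings.warn("all-zero decision-system weights; returning uniform profile")
        return {c: 1.0 / len(CATEGORIES) for c in CATEGORIES}, True
    return {c: abs(v) / denom for c, v in totals.items()}, False


def influence_profiles(obs_model: ObservationModel) -> pd.DataFrame:
    """Per-strategy relative-influence profile (rows sum to 1)."""
    rows = {}
    for sid in obs_model.registry.ids:
        ri, _ = relative_influence(obs_model.weights[sid], obs_model.bank)
        rows[obs_model.registry.get(sid).name] = ri
    return pd.DataFrame(rows).T[list(CATEGORIES)]


# ----------------------------------------------------------------------
# time courses
# ----------------------------------------------------------------------

def time_course(results, level: str = "strategy") -> pd.DataFrame:
    """Per-trial summary across participants of an InferenceResult.

    level='strategy' or 'type': relative frequency of each label per trial
    (rows sum to 1); level='influence': mean relative influence of each
    decision system per trial (rows sum to 1).
    """
    participants = getattr(results, "participants", results)
    if not participants:
        raise ValueError("no participants to summarize")
    if level in ("strategy", "type"):
        rows = []
        for p in participants:
            labels = (p.strategy_names if level == "strategy" else p.type_labels)
            for t, lab in enumerate(labels, start=1):
                rows.append({"trial": t, "label": lab})
        df = pd.DataFrame(rows)
        table = df.groupby(["trial", "label"]).size().unstack(fill_value=0)
        return table.div(table.sum(axis=1), axis=0)
    if level == "influence":
        frames = [p.influence for p in participants if p.influence is not None]
        if not frames:
            raise ValueError("participants carry no influence profiles")
        stacked = pd.concat(frames, keys=range(len(frames)))
        return stacked.groupby(level=1).mean()
    raise ValueError(f"unknown level {level!r}")


# ----------------------------------------------------------------------
# strategy performance
# ----------------------------------------------------------------------

def strategy_performance(strategy: Strategy, env: EnvironmentSpec,
                         n_sims: int = 1000, seed: int = 0) -> float:
    """Mean trial score (path return minus click fees) over simulations."""
    from .environment import trial_score
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_sims):
        tr = simulate_trial(strategy, env, rng)
        total += trial_score(tr.path, tr.ground_truth, tr.n_clicks, env)
    return total / n_sims


def relative_scores(scores: Dict[int, float] | Sequence[float]) -> Dict[int, float]:
    """Min-max normalized scores r^rel in [0, 1] (best = 1, worst = 0)."""
    if isinstance(scores, dict):
        keys, vals = list(scores.keys()), np.array(list(scores.values()), float)
    else:
        keys, vals = list(range(len(scores))), np.asarray(scores, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("all strategies scored identically; r_rel set to 1")
        return {k: 1.0 for k in keys}
    rel = (vals - lo) / (hi - lo)
    return {k: float(r) for k, r in zip(keys, rel)}


# ----------------------------------------------------------------------
# generic statistical utilities
# ----------------------------------------------------------------------

def proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """Two-sample z-test for proportions; returns (z, two-sided p)."""
    p1, p2 = k1 / n1, k2 / n2
    p = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * norm.sf(abs(z)))


def wilcoxon_signed_rank(x, y=None):
    """Thin wrapper over scipy's Wilcoxon signed-rank test."""
    return wilcoxon(x, y)
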