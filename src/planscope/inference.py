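"""Hidden-Markov inference of trial-by-trial strategy sequences.

The latent state on trial t is the strategy S_t; the observation is that
trial's click sequence. The first strategy is uniform over the strategy
set. Under the *abrupt* transition prior a strategy is repeated with
probability p_stay and otherwise jumps uniformly to one of the other
strategies. A *gradual* variant (a documented stand-in used only for
prior comparison) makes transition probability proportional to
exp(-Δ(s_i, s_j)/bandwidth) with Δ the symmetrized-KL strategy distance.

The MAP sequence is decoded with the Viterbi algorithm. p_stay is fitted
by grid search at resolution 0.02 and the softmax temperature τ by a
derivative-free search with a 50-evaluation budget, both maximizing the
joint probability of the MAP sequence; the schedule alternates once
(τ at p_stay = 0.5, then p_stay, then τ again).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .observation import ObservationModel, ParticipantCache
from .strategies import Trial

__all__ = [
    "TransitionPrior",
    "transition_matrix",
    "joint_log_prob",
    "viterbi_map",
    "fit_p_stay",
    "fit_temperature",
    "compare_priors",
    "ParticipantResult",
    "InferenceResult",
    "StrategyInference",
    "PSTAY_GRID",
]

#: p_stay candidates: resolution 0.02 on [0, 1] (51 values).
PSTAY_GRID = np.round(np.arange(0, 51) * 0.02, 10)

_DEFAULT_TAU_RANGE = (1e-2, 1e2)
_TAU_BUDGET = 50


@dataclass
class TransitionPrior:
    """Prior over strategy transitions between consecutive trials."""

    kind: str = "abrupt"
    p_stay: float = 0.5
    bandwidth: float = 1.0
    distances: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("abrupt", "gradual"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind == "abrupt" and not (0.0 <= self.p_stay <= 1.0):
            raise ValueError("p_stay must lie in [0, 1]")
        if self.kind == "gradual":
            if self.distances is None:
                raise ValueError("gradual prior requires a strategy distance matrix")
            if self.bandwidth <= 0:
                raise ValueError("bandwidth must be positive")


def transition_matrix(prior: TransitionPrior, n_strategies: int) -> np.ndarray:
    """Row-stochastic strategy transition matrix implied by the prior."""
    n = n_strategies
    if n < 2:
        raise ValueError("need at least 2 strategies")
    if prior.kind == "abrupt":
        off = (1.0 - prior.p_stay) / (n - 1)
        m = np.full((n, n), off)
        np.fill_diagonal(m, prior.p_stay)
        return m
    d = np.asarray(prior.distances, dtype=float)
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric n x n")
    m = np.exp(-d / prior.bandwidth)
    return m / m.sum(axis=1, keepdims=True)


def _log_transition(prior: TransitionPrior, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(transition_matrix(prior, n))


def viterbi_map(loglik: np.ndarray, log_trans: np.ndarray,
                log_init: Optional[np.ndarray] = None) -> Tuple[np.ndarray, float]:
    """MAP state sequence for per-trial log-likelihoods ``loglik`` (T, S).

    Ties are broken toward the lowest strategy id at every backtrack step,
    making the decode deterministic.
    """
    T, S = loglik.shape
    if log_init is None:
        log_init = np.full(S, -np.log(S))
    delta = log_init + loglik[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans          # (from, to)
        back[t] = np.argmax(cand, axis=0)          # first max -> lowest id
        delta = cand[back[t], np.arange(S)] + loglik[t]
    seq = np.zeros(T, dtype=int)
    seq[-1] = int(np.argmax(delta))
    logp = float(delta[seq[-1]])
    for t in range(T - 1, 0, -1):
        seq[t - 1] = back[t, seq[t]]
    return seq, logp


def joint_log_prob(sequence: Sequence[int], trials_or_loglik, prior: TransitionPrior,
                   obs_model: Optional[ObservationModel] = None,
                   tau: float = 1.0) -> float:
    """log P(sequence, data) under the joint model (uniform initial state).

    ``trials_or_loglik`` is either a list of Trials (scored through
    ``obs_model``) or a precomputed (T, S) log-likelihood matrix.
    """
    seq = np.asarray(sequence, dtype=int)
    if isinstance(trials_or_loglik, np.ndarray):
        loglik = trials_or_loglik
    else:
        trials = trials_or_loglik
        if len(trials) != len(seq):
            raise ValueError("sequence and trials must have equal length")
        loglik = obs_model.participant_cache(trials).loglik_matrix(tau)
    if loglik.shape[0] != len(seq):
        raise ValueError("sequence and likelihood matrix length mismatch")
    S = loglik.shape[1]
    log_trans = _log_transition(prior, S)
    total = -np.log(S) + float(loglik[0, seq[0]])
    for t in range(1, len(seq)):
        total += float(log_trans[seq[t - 1], seq[t]] + loglik[t, seq[t]])
    return total


# ----------------------------------------------------------------------
# hyperparameter fitting
# ----------------------------------------------------------------------

def _map_objective(caches: Sequence[ParticipantCache], prior: TransitionPrior,
                   tau: float) -> float:
    """Summed MAP joint log-probability across participants."""
    n = caches[0].scores.shape[1]
    log_trans = _log_transition(prior, n)
    total = 0.0
    for c in caches:
        _, logp = viterbi_map(c.loglik_matrix(tau), log_trans)
        total += logp
    return total


def fit_p_stay(caches_or_trials, obs_model: Optional[ObservationModel] = None,
               tau: float = 1.0, grid: np.ndarray = PSTAY_GRID) -> float:
    """Grid-search p_stay maximizing the MAP joint probability (ties -> smallest)."""
    caches = _as_caches(caches_or_trials, obs_model)
    best_p, best_val = None, -np.inf
    for p in grid:
        val = _map_objective(caches, TransitionPrior("abrupt", p_stay=float(p)), tau)
        if val > best_val + 1e-9:
            best_p, best_val = float(p), val
    return best_p


def fit_temperature(caches_or_trials, prior: TransitionPrior,
                    obs_model: Optional[ObservationModel] = None,
                    tau_range: Tuple[float, float] = _DEFAULT_TAU_RANGE,
                    budget: int = _TAU_BUDGET, seed: int = 0) -> float:
    """Derivative-free search for τ over a log-spaced range.

    Scans a log grid, then refines around the best grid point with a
    bounded scalar minimizer; the total evaluation budget is ``budget``.
    The procedure is deterministic (``seed`` is accepted for interface
    uniformity).
    """
    caches = _as_caches(caches_or_trials, obs_model)
    lo, hi = np.log10(tau_range[0]), np.log10(tau_range[1])
    n_grid = max(4, budget // 3)
    grid = np.logspace(lo, hi, n_grid)
    vals = [_map_objective(caches, prior, t) for t in grid]
    k = int(np.argmax(vals))
    left = np.log10(grid[max(k - 1, 0)])
    right = np.log10(grid[min(k + 1, n_grid - 1)])
    if left == right:
        return float(grid[k])
    res = minimize_scalar(
        lambda lt: -_map_objective(caches, prior, 10.0 ** lt),
        bounds=(left, right), method="bounded",
        options={"maxiter": max(budget - n_grid, 5), "xatol": 1e-3})
    tau_ref = float(10.0 ** res.x)
    if -res.fun >= vals[k]:
        return tau_ref
    return float(grid[k])


def _as_caches(caches_or_trials, obs_model) -> List[ParticipantCache]:
    if isinstance(caches_or_trials, ParticipantCache):
        return [caches_or_trials]
    seq = list(caches_or_trials)
    if seq and isinstance(seq[0], ParticipantCache):
        return seq
    if seq and isinstance(seq[0], Trial):
        return [obs_model.participant_cache(seq)]
    # list of trial lists (one per participant)
    return [obs_model.participant_cache(trials) for trials in seq]


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

@dataclass
class ParticipantResult:
    participant_id: str
    map_sequence: np.ndarray
    p_stay: float
    tau: float
    log_prob: float
    strategy_names: List[str] = field(default_factory=list)
    type_labels: List[str] = field(default_factory=list)
    influence: Optional[pd.DataFrame] = None  # per-trial RI per category


@dataclass
class InferenceResult:
    """MAP strategy sequences and fitted hyperparameters for a dataset."""

    participants: List[ParticipantResult]
    feature_manifest_hash: str = ""
    strategy_manifest_hash: str = ""

    def sequence_table(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            for t, sid in enumerate(p.map_sequence, start=1):
                rows.append({
                    "participant": p.participant_id, "trial": t,
                    "strategy_id": int(sid),
                    "strategy_name": p.strategy_names[t - 1] if p.strategy_names else "",
                    "type_label": p.type_labels[t - 1] if p.type_labels else "",
                })
        return pd.DataFrame(rows)

    def hyperparameter_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"participant": p.participant_id, "p_stay": p.p_stay,
             "tau": p.tau, "map_log_prob": p.log_prob}
            for p in self.participants
        ])


class StrategyInference:
    """End-to-end per-participant strategy-sequence inference."""

    def __init__(self, obs_model: ObservationModel,
                 prior_kind: str = "abrupt",
                 grid: np.ndarray = PSTAY_GRID,
                 tau_range: Tuple[float, float] = _DEFAULT_TAU_RANGE,
                 tau_budget: int = _TAU_BUDGET,
                 shared_hyperparams: bool = False,
                 gradual_distances: Optional[np.ndarray] = None,
                 compute_influence: bool = True):
        self.obs_model = obs_model
        self.prior_kind = prior_kind
        self.grid = grid
        self.tau_range = tau_range
        self.tau_budget = tau_budget
        self.shared_hyperparams = shared_hyperparams
        self.gradual_distances = gradual_distances
        self.compute_influence = compute_influence

    def _make_prior(self, p_stay: float = 0.5, bandwidth: float = 1.0) -> TransitionPrior:
        if self.prior_kind == "abrupt":
            return TransitionPrior("abrupt", p_stay=p_stay)
        return TransitionPrior("gradual", bandwidth=bandwidth,
                               distances=self.gradual_distances)

    def _fit_hyperparams(self, caches: List[ParticipantCache]) -> Tuple[float, float]:
        tau0 = fit_temperature(caches, self._make_prior(0.5),
                               tau_range=self.tau_range, budget=self.tau_budget)
        p = fit_p_stay(caches, tau=tau0, grid=self.grid)
        tau = fit_temperature(caches, self._make_prior(p),
                              tau_range=self.tau_range, budget=self.tau_budget)
        return p, tau

    def infer_participant(self, trials: Sequence[Trial], participant_id: str = "p0",
                          p_stay: Optional[float] = None,
                          tau: Optional[float] = None) -> ParticipantResult:
        cache = self.obs_model.participant_cache(trials)
        if p_stay is None or tau is None:
            p_fit, tau_fit = self._fit_hyperparams([cache])
            p_stay = p_fit if p_stay is None else p_stay
            tau = tau_fit if tau is None else tau
        log_trans = _log_transition(self._make_prior(p_stay), self.obs_model.n_strategies)
        seq, logp = viterbi_map(cache.loglik_matrix(tau), log_trans)
        return self._finish(participant_id, seq, p_stay, tau, logp)

    def infer_dataset(self, participant_trials: Dict[str, Sequence[Trial]]) -> InferenceResult:
        results: List[ParticipantResult] = []
        if self.shared_hyperparams:
            caches = [self.obs_model.participant_cache(t)
                      for t in participant_trials.values()]
            p_stay, tau = self._fit_hyperparams(caches)
            log_trans = _log_transition(self._make_prior(p_stay),
                                        self.obs_model.n_strategies)
            for (pid, _), cache in zip(participant_trials.items(), caches):
                seq, logp = viterbi_map(cache.loglik_matrix(tau), log_trans)
                results.append(self._finish(pid, seq, p_stay, tau, logp))
        else:
            for pid, trials in participant_trials.items():
                results.append(self.infer_participant(trials, pid))
        import hashlib, json
        smh = hashlib.sha1(json.dumps(self.obs_model.registry.manifest(),
                                      sort_keys=True, default=str).encode()).hexdigest()[:12]
        return InferenceResult(participants=results,
                               feature_manifest_hash=self.obs_model.bank.manifest_hash(),
                               strategy_manifest_hash=smh)

    def _finish(self, pid: str, seq: np.ndarray, p_stay: float, tau: float,
                logp: float) -> ParticipantResult:
        reg = self.obs_model.registry
        names = [reg.get(int(s)).name for s in seq]
        types = [reg.get(int(s)).type_label for s in seq]
        influence = None
        if self.compute_influence:
            from .analysis import relative_influence
            rows = []
            for s in seq:
                ri, _ = relative_influence(self.obs_model.weights[int(s)],
                                           self.obs_model.bank)
                rows.append(ri)
            influence = pd.DataFrame(rows)
            influence.index = pd.RangeIndex(1, len(seq) + 1, name="trial")
        return ParticipantResult(participant_id=pid, map_sequence=seq,
                                 p_stay=p_stay, tau=tau, log_prob=logp,
                                 strategy_names=names, type_labels=types,
                                 influence=influence)


# ----------------------------------------------------------------------
# prior comparison
# ----------------------------------------------------------------------

def compare_priors(participant_trials, obs_model: ObservationModel,
                   priors: Optional[Sequence[TransitionPrior]] = None,
                   gradual_distances: Optional[np.ndarray] = None,
                   tau: Optional[float] = 1.0,
                   bandwidth_grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Rank candidate transition priors by AIC and BIC.

    For each prior, the transition parameter is fitted by grid search and
    the reported log-likelihood is the joint probability of the data and
    the MAP strategy sequence (emission and transition terms; with
    emission terms alone, priors that agree on the decoded sequence would
    be indistinguishable). k counts the fitted hyperparameters (transition
    parameter and τ) and n is the number of trials.
    """
    caches = _as_caches(participant_trials, obs_model)
    n_trials = sum(c.n_trials for c in caches)
    S = obs_model.n_strategies
    if priors is None:
        priors = []
        priors.append(TransitionPrior("abrupt"))
        if gradual_distances is not None:
            priors.append(TransitionPrior("gradual", bandwidth=1.0,
                                          distances=gradual_distances))
    rows = []
    for prior in priors:
        if prior.kind == "abrupt":
            param = fit_p_stay(caches, tau=tau)
            fitted = TransitionPrior("abrupt", p_stay=param)
        else:
            scale = float(np.median(prior.distances[prior.distances > 0])) \
                if (prior.distances > 0).any() else 1.0
            bws = bandwidth_grid if bandwidth_grid is not None else scale * np.logspace(-2, 2, 25)
            vals = [_map_objective(caches, TransitionPrior("gradual", bandwidth=float(b),
                                                           distances=prior.distances), tau)
                    for b in bws]
            param = float(bws[int(np.argmax(vals))])
            fitted = TransitionPrior("gradual", bandwidth=param,
                                     distances=prior.distances)
        log_trans = _log_transition(fitted, S)
        ll = 0.0
        for c in caches:
            lm = c.loglik_matrix(tau)
            _, logp = viterbi_map(lm, log_trans)
            ll += logp
        k = 2  # transition parameter + temperature
        rows.append({"prior": prior.kind, "fitted_param": param, "log_lik": ll,
                     "k": k, "AIC": 2 * k - 2 * ll,
                     "BIC": k * np.log(n_trials) - 2 * ll})
    return pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)
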