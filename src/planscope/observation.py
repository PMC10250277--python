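"""Softmax observation model: P(click sequence | strategy).

Each strategy is represented by a weight vector over the feature bank.
The propensity of an action c in belief state b is exp(w·f(b,c)/τ),
normalized over the available actions (all uninspected nodes plus
TERMINATE). A trial's likelihood is the product of its per-action
probabilities under the evolving belief, including the terminal action.

Weights are fitted once per strategy at τ = 1 by maximum likelihood from
trials simulated with the strategy's generative procedure; the fit is a
convex ridge-penalized multinomial logit. The inference-time temperature
τ then rescales every strategy's propensities jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .environment import BeliefState, EnvironmentSpec, GroundTruth, apply_click, sample_ground_truth
from .features import FeatureBank
from .strategies import TERMINATE, Strategy, StrategyRegistry, Trial, available_actions, simulate_trial

__all__ = [
    "action_log_prob",
    "trial_log_likelihood",
    "fit_strategy_weights",
    "ObservationModel",
    "average_click_likelihood",
]

_RIDGE = 1e-4


def action_log_prob(w: np.ndarray, tau: float, belief: BeliefState, action: int,
                    bank: FeatureBank) -> float:
    """log P(action | belief) under weights ``w`` at temperature ``tau``."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    actions = available_actions(belief)
    if action not in actions:
        raise ValueError(f"action {action} not available")
    X = bank.feature_matrix(belief, actions)
    scores = X @ np.asarray(w, dtype=float) / tau
    idx = actions.index(action)
    return float(scores[idx] - logsumexp(scores))


def trial_log_likelihood(w: np.ndarray, tau: float, trial: Trial,
                         env: EnvironmentSpec, bank: FeatureBank) -> float:
    """Sum of action log-probabilities over the trial, terminal action included."""
    trial.validate(env)
    total = 0.0
    for belief, action in zip(trial.replay_beliefs(env), trial.actions):
        total += action_log_prob(w, tau, belief, action, bank)
    return total


# ----------------------------------------------------------------------
# design-matrix helpers
# ----------------------------------------------------------------------

def _trial_steps(trial: Trial, env: EnvironmentSpec, bank: FeatureBank
                 ) -> List[Tuple[np.ndarray, int]]:
    """Per step: (feature matrix over available actions, chosen index)."""
    steps = []
    for belief, action in zip(trial.replay_beliefs(env), trial.actions):
        actions = available_actions(belief)
        X = bank.feature_matrix(belief, actions)
        steps.append((X, actions.index(action)))
    return steps


def _pack_steps(steps: Sequence[Tuple[np.ndarray, int]]
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad variable action sets into (N, A_max, F), mask (N, A_max), chosen (N,)."""
    n = len(steps)
    a_max = max(X.shape[0] for X, _ in steps)
    f = steps[0][0].shape[1]
    X = np.zeros((n, a_max, f))
    mask = np.zeros((n, a_max), dtype=bool)
    chosen = np.zeros(n, dtype=int)
    for i, (Xi, ci) in enumerate(steps):
        X[i, : Xi.shape[0]] = Xi
        mask[i, : Xi.shape[0]] = True
        chosen[i] = ci
    return X, mask, chosen


def _nll_and_grad(w: np.ndarray, X: np.ndarray, mask: np.ndarray,
                  chosen: np.ndarray, ridge: float) -> Tuple[float, np.ndarray]:
    scores = X @ w
    scores[~mask] = -np.inf
    lse = logsumexp(scores, axis=1)
    idx = np.arange(len(chosen))
    nll = float(np.sum(lse - scores[idx, chosen]) + ridge * np.dot(w, w))
    p = np.exp(scores - lse[:, None])
    p[~mask] = 0.0
    grad = np.einsum("na,naf->f", p, X) - X[idx, chosen].sum(axis=0) + 2 * ridge * w
    return nll, grad


def fit_strategy_weights(strategy: Strategy, env: EnvironmentSpec, bank: FeatureBank,
                         n_sim: int = 300, seed: int | np.random.Generator = 0,
                         ridge: float = _RIDGE,
                         trials: Optional[Sequence[Trial]] = None) -> np.ndarray:
    """MLE weight vector for ``strategy`` from simulated behavior (τ = 1).

    Maximizes the summed trial log-likelihood of ``n_sim`` trials simulated
    from the strategy's generative procedure; the small L2 ridge keeps
    collinear features identified. Raises if the optimizer fails.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if trials is None:
        trials = [simulate_trial(strategy, env, rng) for _ in range(n_sim)]
    steps: List[Tuple[np.ndarray, int]] = []
    for tr in trials:
        steps.extend(_trial_steps(tr, env, bank))
    X, mask, chosen = _pack_steps(steps)
    w0 = np.zeros(bank.n_features)
    res = minimize(_nll_and_grad, w0, args=(X, mask, chosen, ridge),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-10})
    if not res.success and res.status != 1:  # status 1 = maxiter, still usable
        raise RuntimeError(f"weight fit for {strategy.name!r} failed: {res.message}")
    return res.x


@dataclass
class ParticipantCache:
    """Precomputed per-step propensity scores for one participant's trials.

    ``scores[n, s, a]`` is w_s · f(action a, belief at step n), padded with
    -inf over unavailable action slots; used to evaluate trial likelihoods
    for all strategies at any temperature without touching features again.
    """

    scores: np.ndarray      # (n_steps, n_strategies, a_max)
    chosen: np.ndarray      # (n_steps,)
    trial_of_step: np.ndarray
    n_trials: int

    def loglik_matrix(self, tau: float) -> np.ndarray:
        """(n_trials, n_strategies) log-likelihood at temperature ``tau``."""
        s = self.scores / tau
        lse = logsumexp(s, axis=2)
        idx = np.arange(s.shape[0])
        step_ll = s[idx, :, self.chosen] - lse
        out = np.zeros((self.n_trials, s.shape[1]))
        np.add.at(out, self.trial_of_step, step_ll)
        return out


class ObservationModel:
    """Fitted softmax click model for a strategy registry."""

    def __init__(self, env: EnvironmentSpec, registry: StrategyRegistry,
                 bank: FeatureBank,
                 weights: Optional[Dict[int, np.ndarray]] = None):
        self.env = env
        self.registry = registry
        self.bank = bank
        self.weights: Dict[int, np.ndarray] = dict(weights or {})

    @property
    def n_strategies(self) -> int:
        return len(self.registry)

    def fit(self, n_sim: int = 300, seed: int = 0, verbose: bool = False) -> "ObservationModel":
        ss = np.random.SeedSequence(seed)
        for s, child in zip(self.registry.strategies, ss.spawn(len(self.registry))):
            self.weights[s.id] = fit_strategy_weights(
                s, self.env, self.bank, n_sim=n_sim,
                seed=np.random.default_rng(child))
            if verbose:
                print(f"fitted weights for {s.name}")
        return self

    def weight_matrix(self) -> np.ndarray:
        """(n_strategies, n_features) in registry order."""
        return np.stack([self.weights[i] for i in self.registry.ids])

    def weights_table(self):
        """Fitted weights as a strategy x feature-name table."""
        import pandas as pd
        names = [s.name for s in self.registry.strategies]
        return pd.DataFrame(self.weight_matrix(), index=names,
                            columns=self.bank.names)

    def save_weights(self, path) -> None:
        """Write the weights table; the feature-manifest hash guards ordering."""
        df = self.weights_table()
        df.insert(0, "feature_manifest", self.bank.manifest_hash())
        df.to_csv(path)

    def load_weights(self, path) -> "ObservationModel":
        import pandas as pd
        df = pd.read_csv(path, index_col=0)
        stored = df.pop("feature_manifest").iloc[0]
        if stored != self.bank.manifest_hash():
            raise ValueError(
                "feature manifest hash mismatch: stored weights were fitted "
                "against a different feature ordering")
        if list(df.columns) != self.bank.names:
            raise ValueError("feature columns do not match the feature bank")
        for s in self.registry.strategies:
            self.weights[s.id] = df.loc[s.name].to_numpy(dtype=float)
        return self

    # -- likelihood -----------------------------------------------------
    def trial_log_likelihood(self, strategy_id: int, tau: float, trial: Trial) -> float:
        return trial_log_likelihood(self.weights[strategy_id], tau, trial,
                                    self.env, self.bank)

    def participant_cache(self, trials: Sequence[Trial]) -> ParticipantCache:
        W = self.weight_matrix()
        steps: List[Tuple[np.ndarray, int]] = []
        trial_of_step: List[int] = []
        for t_idx, tr in enumerate(trials):
            st = _trial_steps(tr, self.env, self.bank)
            steps.extend(st)
            trial_of_step.extend([t_idx] * len(st))
        X, mask, chosen = _pack_steps(steps)
        scores = np.einsum("sf,naf->nsa", W, X)
        scores = np.where(mask[:, None, :], scores, -np.inf)
        return ParticipantCache(scores=scores, chosen=chosen,
                                trial_of_step=np.asarray(trial_of_step),
                                n_trials=len(trials))

    # -- generation -----------------------------------------------------
    def sample_trial(self, strategy_id: int, tau: float, rng,
                     truth: Optional[GroundTruth] = None, t: int = 0) -> Trial:
        """Simulate a trial from the fitted softmax model of a strategy."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        w = self.weights[strategy_id]
        if truth is None:
            truth = sample_ground_truth(self.env, rng)
        belief = BeliefState(self.env)
        actions_taken: List[int] = []
        values: List[float] = []
        while True:
            actions = available_actions(belief)
            X = self.bank.feature_matrix(belief, actions)
            scores = X @ w / tau
            p = np.exp(scores - logsumexp(scores))
            a = int(actions[rng.choice(len(actions), p=p / p.sum())])
            actions_taken.append(a)
            if a == TERMINATE:
                break
            values.append(truth[a])
            belief = apply_click(belief, a, truth)
        evs = belief.path_evs
        best = np.flatnonzero(evs >= evs.max() - 1e-12)
        path = self.env.paths[int(rng.choice(best))]
        return Trial(env_name=self.env.name, ground_truth=truth,
                     actions=tuple(actions_taken), click_values=tuple(values),
                     path=tuple(path), t=t)


@dataclass(frozen=True)
class ClickLikelihood:
    arithmetic: float
    geometric: float


def average_click_likelihood(obs_model: ObservationModel,
                             trials: Sequence[Trial],
                             assignment: Sequence[int],
                             tau: float = 1.0) -> ClickLikelihood:
    """Mean per-action probability under the assigned strategies.

    Returns both the arithmetic mean (primary diagnostic) and the
    geometric mean of the per-action probabilities.
    """
    if len(trials) != len(assignment):
        raise ValueError("one strategy assignment per trial required")
    logs: List[float] = []
    for tr, sid in zip(trials, assignment):
        w = obs_model.weights[sid]
        for belief, action in zip(tr.replay_beliefs(obs_model.env), tr.actions):
            logs.append(action_log_prob(w, tau, belief, action, obs_model.bank))
    logs_arr = np.array(logs)
    return ClickLikelihood(arithmetic=float(np.exp(logs_arr).mean()),
                           geometric=float(np.exp(logs_arr.mean())))
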