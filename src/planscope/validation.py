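"""Simulation studies: strategy recovery and influence-trend recovery.

Synthetic participants are produced by (i) sampling a ground-truth
strategy sequence from a generative model — per-trial random, abrupt
Markov switching, or gradual drift along the strategy-distance ordering —
and (ii) sampling each trial's clicks from the true strategy's fitted
softmax observation model at a generation temperature τ_gen. Running the
full inference pipeline on such data and scoring it against the known
sequences quantifies how well strategies, strategy types, and
decision-system influence trends can be recovered from click data alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .analysis import DistanceMatrix, distance_matrix, relative_influence
from .datasets import ParticipantRecord, ProcessTracingDataset
from .inference import StrategyInference
from .observation import ObservationModel

__all__ = [
    "GenerativeSequenceModel",
    "sample_sequences",
    "generate_participants",
    "RecoveryReport",
    "recovery_experiment",
    "TrendReport",
    "trend_experiment",
    "drift_ordering",
]


@dataclass
class GenerativeSequenceModel:
    """Ground-truth model of how the latent strategy evolves across trials."""

    kind: str  # random_per_trial | abrupt_markov | gradual_drift
    p_stay: float = 0.8
    kernel_width: float = 1.5
    ordering: Optional[np.ndarray] = None  # strategy ids ordered by similarity

    def __post_init__(self) -> None:
        if self.kind not in ("random_per_trial", "abrupt_markov", "gradual_drift"):
            raise ValueError(f"unknown generator kind {self.kind!r}")


def drift_ordering(dmat: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Order strategies along the first principal coordinate of the distances."""
    d = dmat.values if isinstance(dmat, DistanceMatrix) else np.asarray(dmat)
    n = d.shape[0]
    # classical multidimensional scaling
    d2 = d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    coord = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    return np.argsort(coord, kind="stable")


def sample_sequences(model: GenerativeSequenceModel, n_strategies: int,
                     n: int, T: int, rng) -> List[np.ndarray]:
    """Sample ``n`` ground-truth strategy-id sequences of length ``T``."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    S = n_strategies
    out: List[np.ndarray] = []
    if model.kind == "random_per_trial":
        for _ in range(n):
            out.append(rng.integers(0, S, size=T))
        return out
    if model.kind == "abrupt_markov":
        for _ in range(n):
            seq = np.zeros(T, dtype=int)
            seq[0] = rng.integers(0, S)
            for t in range(1, T):
                if rng.random() < model.p_stay:
                    seq[t] = seq[t - 1]
                else:
                    others = [s for s in range(S) if s != seq[t - 1]]
                    seq[t] = others[rng.integers(0, S - 1)]
            out.append(seq)
        return out
    # gradual drift: Gaussian kernel over rank distance in the similarity ordering
    ordering = model.ordering if model.ordering is not None else np.arange(S)
    rank = np.empty(S, dtype=int)
    rank[np.asarray(ordering)] = np.arange(S)
    kern = np.exp(-((rank[:, None] - rank[None, :]) ** 2)
                  / (2.0 * model.kernel_width ** 2))
    kern = kern / kern.sum(axis=1, keepdims=True)
    for _ in range(n):
        seq = np.zeros(T, dtype=int)
        seq[0] = rng.integers(0, S)
        for t in range(1, T):
            seq[t] = rng.choice(S, p=kern[seq[t - 1]])
        out.append(seq)
    return out


def generate_participants(model: GenerativeSequenceModel, obs_model: ObservationModel,
                          n: int, T: int = 31, tau_gen: float = 1.0,
                          seed: int = 0, name: str = "synthetic",
                          id_prefix: str = "p"
                          ) -> Tuple[ProcessTracingDataset, Dict[str, np.ndarray]]:
    """Simulate ``n`` participants; returns (dataset, true strategy sequences)."""
    rng = np.random.default_rng(seed)
    sequences = sample_sequences(model, obs_model.n_strategies, n, T, rng)
    ds = ProcessTracingDataset(
        name=name, env_name=obs_model.env.name,
        provenance={"generator": model.kind, "seed": seed, "tau_gen": tau_gen,
                    "p_stay": model.p_stay if model.kind == "abrupt_markov" else None})
    truth: Dict[str, np.ndarray] = {}
    for i, seq in enumerate(sequences):
        pid = f"{id_prefix}{i}"
        rec = ParticipantRecord(id=pid, condition=model.kind)
        for t, sid in enumerate(seq, start=1):
            rec.trials.append(obs_model.sample_trial(int(sid), tau_gen, rng, t=t))
        ds.participants.append(rec)
        truth[pid] = seq
    return ds, truth


@dataclass
class RecoveryReport:
    """Accuracy of MAP inference against known ground-truth sequences."""

    strategy_accuracy: float
    type_accuracy: float
    confusion: pd.DataFrame
    per_generator: Dict[str, Dict[str, float]]
    n_participants: int
    n_trials: int
    seed: int

    def summary(self) -> dict:
        return {
            "strategy_accuracy": self.strategy_accuracy,
            "type_accuracy": self.type_accuracy,
            "n_participants": self.n_participants,
            "n_trials": self.n_trials,
            "per_generator": self.per_generator,
        }


def _score_inference(obs_model: ObservationModel, inference: StrategyInference,
                     dataset: ProcessTracingDataset,
                     truth: Dict[str, np.ndarray]) -> Tuple[int, int, int, np.ndarray]:
    reg = obs_model.registry
    S = len(reg)
    types = reg.type_labels()
    confusion = np.zeros((S, S), dtype=int)
    hit_s = hit_t = total = 0
    result = inference.infer_dataset(dataset.participant_trials())
    for p in result.participants:
        true_seq = truth[p.participant_id]
        for true_id, map_id in zip(true_seq, p.map_sequence):
            confusion[int(true_id), int(map_id)] += 1
            total += 1
            hit_s += int(true_id == map_id)
            hit_t += int(types[int(true_id)] == types[int(map_id)])
    return hit_s, hit_t, total, confusion


def recovery_experiment(obs_model: ObservationModel,
                        generators: Optional[Sequence[GenerativeSequenceModel]] = None,
                        n_per_generator: int = 50, T: int = 31,
                        tau_gen: float = 1.0, seed: int = 0,
                        drift_n_mc: int = 200,
                        inference: Optional[StrategyInference] = None) -> RecoveryReport:
    """Generate → infer → score strategy and strategy-type recovery.

    Default generators: per-trial random, abrupt Markov switching with
    p_stay = 0.8, and gradual drift along the strategy-distance ordering.
    """
    ss = np.random.SeedSequence(seed)
    sub = ss.generate_state(4) % (2 ** 31)
    if generators is None:
        dmat = distance_matrix(obs_model, n_mc=drift_n_mc, seed=int(sub[0]))
        generators = [
            GenerativeSequenceModel("random_per_trial"),
            GenerativeSequenceModel("abrupt_markov", p_stay=0.8),
            GenerativeSequenceModel("gradual_drift", ordering=drift_ordering(dmat)),
        ]
    if inference is None:
        inference = StrategyInference(obs_model, compute_influence=False)
    reg = obs_model.registry
    S = len(reg)
    total_conf = np.zeros((S, S), dtype=int)
    hits_s = hits_t = total = 0
    per_gen: Dict[str, Dict[str, float]] = {}
    for gi, gen in enumerate(generators):
        ds, truth = generate_participants(
            gen, obs_model, n=n_per_generator, T=T, tau_gen=tau_gen,
            seed=int(sub[1]) + gi, name=f"recovery_{gen.kind}",
            id_prefix=f"{gen.kind}_")
        hs, ht, tot, conf = _score_inference(obs_model, inference, ds, truth)
        per_gen[gen.kind] = {"strategy_accuracy": hs / tot,
                             "type_accuracy": ht / tot, "n_trials": tot}
        hits_s += hs
        hits_t += ht
        total += tot
        total_conf += conf
    names = [s.name for s in reg.strategies]
    confusion = pd.DataFrame(total_conf, index=pd.Index(names, name="true"),
                             columns=pd.Index(names, name="inferred"))
    return RecoveryReport(strategy_accuracy=hits_s / total,
                          type_accuracy=hits_t / total,
                          confusion=confusion, per_generator=per_gen,
                          n_participants=n_per_generator * len(generators),
                          n_trials=total, seed=seed)


# ----------------------------------------------------------------------
# decision-system trend recovery
# ----------------------------------------------------------------------

@dataclass
class TrendReport:
    factor: str
    trend: str
    true_curve: np.ndarray        # mean true RI per trial
    inferred_curve: np.ndarray    # mean inferred RI per trial
    spearman_rho: float           # trial index vs mean inferred RI
    per_sequence_rho: np.ndarray
    n_sequences: int
    seed: int


def _factor_ri(obs_model: ObservationModel, factor: str) -> np.ndarray:
    vals = []
    for sid in obs_model.registry.ids:
        ri, _ = relative_influence(obs_model.weights[sid], obs_model.bank)
        vals.append(ri[factor])
    return np.array(vals)


def trend_experiment(obs_model: ObservationModel, factor: str,
                     trend: str = "increasing", n_sequences: int = 50,
                     tau_gen: float = 1.0, seed: int = 0,
                     inference: Optional[StrategyInference] = None) -> TrendReport:
    """Recover a constructed trend in one decision system's relative influence.

    Monotone trends use each strategy exactly once, ordered by the factor's
    contribution; the constant trend samples each sequence from one of up
    to three percentile groups (33rd/67th/100th) of the factor's influence.
    Sequence length equals the number of strategies.
    """
    if trend not in ("increasing", "decreasing", "constant"):
        raise ValueError(f"unknown trend {trend!r}")
    rng = np.random.default_rng(seed)
    ri = _factor_ri(obs_model, factor)
    S = obs_model.n_strategies
    T = S
    sequences: List[np.ndarray] = []
    if trend in ("increasing", "decreasing"):
        base = np.argsort(ri, kind="stable")
        if trend == "decreasing":
            base = base[::-1]
        sequences = [base.copy() for _ in range(n_sequences)]
    else:
        edges = np.percentile(ri, [33, 67])
        groups = [np.flatnonzero(ri <= edges[0]),
                  np.flatnonzero((ri > edges[0]) & (ri <= edges[1])),
                  np.flatnonzero(ri > edges[1])]
        groups = [g for g in groups if len(g) > 0]
        for _ in range(n_sequences):
            g = groups[rng.integers(0, len(groups))]
            sequences.append(rng.choice(g, size=T, replace=True))
    if inference is None:
        inference = StrategyInference(obs_model, compute_influence=False)
    true_ri = np.zeros((n_sequences, T))
    inf_ri = np.zeros((n_sequences, T))
    rhos = np.zeros(n_sequences)
    for i, seq in enumerate(sequences):
        trials = [obs_model.sample_trial(int(s), tau_gen, rng, t=t + 1)
                  for t, s in enumerate(seq)]
        res = inference.infer_participant(trials, participant_id=f"seq{i}")
        true_ri[i] = ri[seq]
        inf_ri[i] = ri[res.map_sequence]
        rho = spearmanr(np.arange(T), inf_ri[i]).statistic
        rhos[i] = 0.0 if np.isnan(rho) else rho
    mean_curve = inf_ri.mean(axis=0)
    rho_all = spearmanr(np.arange(T), mean_curve).statistic
    return TrendReport(factor=factor, trend=trend,
                       true_curve=true_ri.mean(axis=0),
                       inferred_curve=mean_curve,
                       spearman_rho=0.0 if np.isnan(rho_all) else float(rho_all),
                       per_sequence_rho=rhos, n_sequences=n_sequences, seed=seed)
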