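"""Reading and writing process-tracing datasets.

The canonical on-disk schema (JSON) mirrors Mouselab-MDP click logs::

    {"dataset": ..., "env": <preset name>, "provenance": {...},
     "participants": [
        {"id": ..., "condition": ..., "block": ...,
         "trials": [{"t": 1, "ground_truth": {"<node>": reward, ...},
                     "clicks": [{"node": n, "value": v}, ...],
                     "path": [0, ...]}]}]}

A long-format CSV twin (one row per action) is provided for
interoperability. Revealed click values are cross-checked against the
stored ground truth on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .environment import EnvironmentSpec, GroundTruth, build_environment
from .strategies import TERMINATE, Trial

__all__ = [
    "ParticipantRecord",
    "ProcessTracingDataset",
    "IntegrityError",
    "read_dataset",
    "write_dataset",
]


class IntegrityError(ValueError):
    """A dataset record violates a trial invariant."""


@dataclass
class ParticipantRecord:
    id: str
    condition: str = "none"
    block: str = "all"
    trials: List[Trial] = field(default_factory=list)


@dataclass
class ProcessTracingDataset:
    name: str
    env_name: str
    participants: List[ParticipantRecord] = field(default_factory=list)
    provenance: Dict = field(default_factory=dict)

    def environment(self) -> EnvironmentSpec:
        return build_environment(self.env_name)

    def participant_trials(self, block: Optional[str] = None,
                           condition: Optional[str] = None) -> Dict[str, List[Trial]]:
        out = {}
        for p in self.participants:
            if block is not None and p.block != block:
                continue
            if condition is not None and p.condition != condition:
                continue
            out[p.id] = p.trials
        return out

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def validate(self) -> None:
        if not self.participants:
            raise IntegrityError("dataset has no participants")
        env = self.environment()
        for p in self.participants:
            for i, tr in enumerate(p.trials, start=1):
                if tr.t != i:
                    raise IntegrityError(
                        f"participant {p.id}: trial indices not contiguous at {i}")
                try:
                    tr.validate(env)
                except ValueError as exc:
                    raise IntegrityError(
                        f"participant {p.id}, trial {i}: {exc}") from exc


def _trial_to_dict(tr: Trial) -> dict:
    return {
        "t": tr.t,
        "ground_truth": {str(k): v for k, v in tr.ground_truth.rewards.items()},
        "clicks": [{"node": int(n), "value": float(v)}
                   for n, v in zip(tr.clicks, tr.click_values)],
        "path": list(tr.path),
    }


def _trial_from_dict(d: dict, env_name: str) -> Trial:
    truth = GroundTruth({int(k): float(v) for k, v in d["ground_truth"].items()})
    clicks = [int(c["node"]) for c in d["clicks"]]
    values = [float(c["value"]) for c in d["clicks"]]
    return Trial(env_name=env_name, ground_truth=truth,
                 actions=tuple(clicks) + (TERMINATE,),
                 click_values=tuple(values), path=tuple(d["path"]),
                 t=int(d.get("t", 0)))


def write_dataset(dataset: ProcessTracingDataset, path, dialect: str = "json") -> None:
    path = Path(path)
    if dialect == "json":
        payload = {
            "dataset": dataset.name,
            "env": dataset.env_name,
            "provenance": dataset.provenance,
            "participants": [
                {"id": p.id, "condition": p.condition, "block": p.block,
                 "trials": [_trial_to_dict(t) for t in p.trials]}
                for p in dataset.participants
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif dialect == "csv":
        rows = []
        for p in dataset.participants:
            for tr in p.trials:
                for step, a in enumerate(tr.actions):
                    row = {"dataset": dataset.name, "env": dataset.env_name,
                           "participant": p.id, "condition": p.condition,
                           "block": p.block, "trial": tr.t, "step": step,
                           "node": int(a), "value": "", "path": "",
                           "ground_truth": ""}
                    if a != TERMINATE:
                        row["value"] = tr.click_values[step]
                    else:
                        row["path"] = "|".join(map(str, tr.path))
                        row["ground_truth"] = json.dumps(
                            {str(k): v for k, v in tr.ground_truth.rewards.items()})
                    rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_dataset(path, dialect: str = "json") -> ProcessTracingDataset:
    """Read and validate a process-tracing dataset."""
    path = Path(path)
    if dialect == "json":
        payload = json.loads(path.read_text())
        ds = ProcessTracingDataset(
            name=payload["dataset"], env_name=payload["env"],
            provenance=payload.get("provenance", {}))
        for p in payload["participants"]:
            rec = ParticipantRecord(id=str(p["id"]),
                                    condition=p.get("condition", "none"),
                                    block=p.get("block", "all"))
            rec.trials = [_trial_from_dict(t, ds.env_name) for t in p["trials"]]
            ds.participants.append(rec)
    elif dialect == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
        df["trial"] = df["trial"].astype(int)
        df["step"] = df["step"].astype(int)
        df["node"] = df["node"].astype(int)
        ds = ProcessTracingDataset(name=str(df["dataset"].iloc[0]),
                                   env_name=str(df["env"].iloc[0]))
        for pid, pdf in df.groupby("participant", sort=False):
            rec = ParticipantRecord(id=str(pid),
                                    condition=str(pdf["condition"].iloc[0]),
                                    block=str(pdf["block"].iloc[0]))
            for t, tdf in pdf.groupby("trial", sort=True):
                tdf = tdf.sort_values("step")
                term = tdf[tdf["node"] == TERMINATE].iloc[0]
                truth = GroundTruth({int(k): float(v) for k, v in
                                     json.loads(term["ground_truth"]).items()})
                clicks = tdf[tdf["node"] != TERMINATE]
                rec.trials.append(Trial(
                    env_name=ds.env_name, ground_truth=truth,
                    actions=tuple(int(n) for n in clicks["node"]) + (TERMINATE,),
                    click_values=tuple(float(v) for v in clicks["value"]),
                    path=tuple(int(x) for x in str(term["path"]).split("|")),
                    t=int(t)))
            ds.participants.append(rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    ds.validate()
    return ds
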