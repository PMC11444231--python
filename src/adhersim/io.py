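"""Reading and writing session artifacts.

Participant tables are CSV, event logs are JSON Lines (one dose or score
event per line), and configuration files are YAML.  Malformed or truncated
files raise :class:`ArtifactError` with the offending line number — never a
silent partial read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from adhersim.agents import AgentParams
from adhersim.env import DoseEvent, DoseOutcome, SessionConfig
from adhersim.harness import ExperimentPlan, ParticipantRecord, ScoreEvent, records_to_frame

RECORD_COLUMNS = [
    "participant_id",
    "condition",
    "seed",
    "adherence_rate",
    "n_on_time",
    "n_off_time",
    "n_wrong_code",
    "n_missed",
    "relapse_round",
    "final_score",
    "earnings",
]


class ArtifactError(ValueError):
    """Raised for malformed or truncated artifact files."""


def write_records_csv(records: list[ParticipantRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: Union[str, Path]) -> list[ParticipantRecord]:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parse error types
        raise ArtifactError(f"{path}: cannot parse participant table: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ArtifactError(f"{path}: missing columns {missing}")
    records = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            relapse = row.relapse_round
            relapse = None if pd.isna(relapse) else int(relapse)
            records.append(
                ParticipantRecord(
                    participant_id=str(row.participant_id),
                    condition=str(row.condition),
                    seed=int(row.seed),
                    adherence_rate=float(row.adherence_rate),
                    n_on_time=int(row.n_on_time),
                    n_off_time=int(row.n_off_time),
                    n_wrong_code=int(row.n_wrong_code),
                    n_missed=int(row.n_missed),
                    relapse_round=relapse,
                    final_score=int(row.final_score),
                    earnings=float(row.earnings),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ArtifactError(f"{path}:{lineno}: bad record row: {exc}") from exc
    return records


def _event_to_dict(event) -> dict:
    d = asdict(event)
    if isinstance(event, DoseEvent):
        d["type"] = "dose"
        d["outcome"] = event.outcome.value
    elif isinstance(event, ScoreEvent):
        d["type"] = "score"
    else:
        raise TypeError(f"unknown event type {type(event)!r}")
    return d


def _event_from_dict(d: dict):
    kind = d.pop("type", None)
    if kind == "dose":
        d["outcome"] = DoseOutcome(d["outcome"])
        return DoseEvent(**d)
    if kind == "score":
        return ScoreEvent(**d)
    raise ValueError(f"unknown event type {kind!r}")


def write_events_jsonl(
    events_by_participant: dict[str, list], path: Union[str, Path]
) -> None:
    """One JSON object per line, tagged with participant id and event type."""
    with open(path, "w") as fh:
        for pid, events in events_by_participant.items():
            for event in events:
                d = _event_to_dict(event)
                d["participant_id"] = pid
                fh.write(json.dumps(d) + "\n")


def read_events_jsonl(path: Union[str, Path]) -> dict[str, list]:
    events_by_participant: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                pid = d.pop("participant_id")
                event = _event_from_dict(d)
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ArtifactError(f"{path}:{lineno}: bad event line: {exc}") from exc
            events_by_participant.setdefault(pid, []).append(event)
    return events_by_participant


def write_config_yaml(
    path: Union[str, Path],
    config: SessionConfig,
    agent: AgentParams | None = None,
    plan: ExperimentPlan | None = None,
) -> None:
    doc: dict = {"session": asdict(config)}
    if agent is not None:
        doc["agent"] = asdict(agent)
    if plan is not None:
        doc["plan"] = {"arm_sizes": dict(plan.arm_sizes), "master_seed": plan.master_seed}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_config_yaml(
    path: Union[str, Path],
) -> tuple[SessionConfig, AgentParams | None, ExperimentPlan | None]:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ArtifactError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ArtifactError(f"{path}: config must be a mapping")
    try:
        config = SessionConfig(**doc.get("session", {}))
        agent = AgentParams(**doc["agent"]) if "agent" in doc else None
        plan = (
            ExperimentPlan(
                arm_sizes=doc["plan"].get("arm_sizes", {}),
                master_seed=doc["plan"].get("master_seed", 0),
            )
            if "plan" in doc
            else None
        )
    except (TypeError, ValueError) as exc:
        raise ArtifactError(f"{path}: bad config values: {exc}") from exc
    return config, agent, plan
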