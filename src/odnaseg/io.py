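"""Reading and writing schedule / parameter files (YAML or JSON).

A schedule file is a mapping with an optional ``label`` and an ``events``
list, one entry per mechanism event using the MechanismEvent field names::

    label: two-step
    events:
      - kind: division
        n1: 1000
      - kind: turnover_epoch
        n1: 500
        duration_days: 1.0
        turnover_rate: 1.0
        frag_fraction: 1.0

A simulator parameter file is a flat mapping of SimParams field names;
missing keys take the printed defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .ssa import SimParams
from .variance import MechanismEvent, Schedule

__all__ = ["load_schedule", "load_sim_params", "save_schedule"]


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level, got {type(data).__name__}")
    return data


def load_schedule(path: str | Path) -> Schedule:
    """Load and validate an event schedule, with per-entry error context."""
    data = _load_mapping(path)
    if "events" not in data or not isinstance(data["events"], list):
        raise ValueError(f"{path}: schedule file needs an 'events' list")
    valid_fields = {f.name for f in dataclasses.fields(MechanismEvent)}
    events = []
    for i, entry in enumerate(data["events"]):
        if not isinstance(entry, dict):
            raise ValueError(f"{path}: events[{i}] is not a mapping")
        unknown = set(entry) - valid_fields
        if unknown:
            raise ValueError(
                f"{path}: events[{i}] has unknown key(s) {sorted(unknown)}; "
                f"valid keys: {sorted(valid_fields)}"
            )
        try:
            events.append(MechanismEvent(**entry))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: events[{i}]: {exc}") from exc
    try:
        return Schedule(events, label=str(data.get("label", Path(path).stem)))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_schedule(schedule: Schedule, path: str | Path) -> None:
    payload = {
        "label": schedule.label,
        "events": [
            {
                k: (v.value if hasattr(v, "value") else v)
                for k, v in dataclasses.asdict(e).items()
            }
            for e in schedule.events
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_sim_params(path: str | Path) -> SimParams:
    """Load simulator parameters; unspecified keys keep the defaults."""
    data = _load_mapping(path)
    valid_fields = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(data) - valid_fields
    if unknown:
        raise ValueError(
            f"{path}: unknown parameter(s) {sorted(unknown)}; "
            f"valid keys: {sorted(valid_fields)}"
        )
    try:
        return SimParams(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
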