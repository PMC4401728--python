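"""Readers and writers for the documented CSV/JSON formats.

Trial lists and response logs are plain comma-separated UTF-8 with a
mandatory header; sequences are serialized space-separated so the syllables
stay human-readable.  Configs and reports are JSON.  Every writer/reader
pair round-trips losslessly, and schema violations are reported with the
offending row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .design import DesignConfig, ExperimentDesign, Trial
from .errors import SchemaError
from .grammar import DependencyType
from .simulate import Response, ResponseLog

TRIAL_COLUMNS = ["index", "phase", "length_class", "sequence", "label",
                 "foil_subset", "repeat_probe", "grammar_of_sequence"]
RESPONSE_COLUMNS = ["participant_id", "group", "trial_index", "answer"]


def write_trials_csv(design: ExperimentDesign, path: str | Path) -> None:
    rows = []
    for t in design.trials:
        rows.append({
            "index": t.index, "phase": t.phase, "length_class": t.length_class,
            "sequence": " ".join(t.sequence), "label": t.label,
            "foil_subset": t.foil_subset,
            "repeat_probe": int(t.repeat_probe),
            "grammar_of_sequence": (t.grammar_of_sequence.value
                                    if t.grammar_of_sequence else "none"),
        })
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def write_design_config_json(design: ExperimentDesign, path: str | Path) -> None:
    cfg = dataclasses.asdict(design.config)
    cfg["lengths"] = list(cfg["lengths"])
    payload = {"experiment": design.experiment, "group": design.group.value,
               "seed": design.seed, "config": cfg}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_design(trials_path: str | Path,
                config_path: str | Path | None = None) -> ExperimentDesign:
    """Reconstruct a design from its trial CSV (and optional config JSON).

    Without the config JSON, the experiment number and trained group are
    inferred from the trials (foil subsets imply experiment 2; the grammar
    of the correct test trials is the trained grammar) and count
    parameters fall back to defaults.
    """
    try:
        df = pd.read_csv(trials_path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise SchemaError(f"cannot read trial CSV {trials_path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial CSV {trials_path} missing column(s) {missing}")
    trials: list[Trial] = []
    for i, row in df.iterrows():
        try:
            g = row["grammar_of_sequence"]
            trials.append(Trial(
                index=int(row["index"]), sequence=tuple(row["sequence"].split()),
                phase=row["phase"], length_class=row["length_class"],
                label=row["label"], foil_subset=row["foil_subset"],
                repeat_probe=bool(int(row["repeat_probe"])),
                grammar_of_sequence=None if g == "none" else DependencyType.parse(g)))
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"trial CSV {trials_path} row {i + 2}: {exc}") from exc

    if config_path is not None:
        payload = json.loads(Path(config_path).read_text(encoding="utf-8"))
        cfg_d = payload["config"]
        cfg_d["lengths"] = tuple(cfg_d["lengths"])
        return ExperimentDesign(int(payload["experiment"]),
                                DependencyType.parse(payload["group"]),
                                int(payload["seed"]), DesignConfig(**cfg_d), trials)

    experiment = 2 if any(t.foil_subset != "none" for t in trials) else 1
    group = next((t.grammar_of_sequence for t in trials
                  if t.phase == "test" and t.label == "correct"
                  and t.grammar_of_sequence is not None), None)
    if group is None:
        raise SchemaError(f"trial CSV {trials_path}: cannot infer the trained grammar")
    return ExperimentDesign(experiment, group, -1, DesignConfig(), trials)


def write_responses_csv(logs: Sequence[ResponseLog], path: str | Path) -> None:
    rows = [{"participant_id": log.participant_id, "group": log.group.value,
             "trial_index": r.trial_index, "answer": "yes" if r.answer else "no"}
            for log in logs for r in log.responses]
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)


def read_responses_csv(path: str | Path) -> list[ResponseLog]:
    """Parse a response CSV into per-participant logs (row order preserved —
    it is the presentation order)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise SchemaError(f"cannot read response CSV {path}: {exc}") from exc
    if df.empty and not set(RESPONSE_COLUMNS) <= set(df.columns):
        return []
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"response CSV {path} missing column(s) {missing}")
    logs: dict[str, ResponseLog] = {}
    for i, row in df.iterrows():
        pid = row["participant_id"]
        ans = row["answer"].strip().lower()
        if ans not in ("yes", "no", "1", "0", "true", "false"):
            raise SchemaError(f"response CSV {path} row {i + 2}: bad answer {row['answer']!r}")
        try:
            idx = int(row["trial_index"])
            group = DependencyType.parse(row["group"])
        except ValueError as exc:
            raise SchemaError(f"response CSV {path} row {i + 2}: {exc}") from exc
        log = logs.setdefault(pid, ResponseLog(pid, group, policy="unknown"))
        log.responses.append(Response(idx, ans in ("yes", "1", "true")))
    return list(logs.values())


def write_manifest_json(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")


def write_report_json(report_dict: dict, path: str | Path) -> None:
    def default(o):
        if hasattr(o, "item"):
            return o.item()
        if isinstance(o, bool):
            return o
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report_dict, indent=2, default=default) + "\n",
                          encoding="utf-8")
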