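"""End-to-end pipeline: digest -> K_stat features -> train / predict,
plus the sequential binary-classification protocol.

``run_pipeline`` ties the stages together under one configuration and
writes machine-readable artifacts (feature table, model or predictions,
JSON report) stamped with a configuration hash and the seeds used, so runs
are reproducible byte for byte.

``sequential_classify`` applies an ordered tree of binary logistic models to
one protein's feature row — e.g. membrane vs. soluble, then monotopic vs.
transmembrane, then single- vs. multi-pass, then α-helical vs. β-barrel —
emitting the full decision trace.  The tree is user-declared data (JSON),
since the appropriate sequence of tests depends on what is already known
about the protein.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .classify import BinaryLogisticModel, predict_binary, stepwise_logistic
from .digestion import load_fasta, prepare_dataset
from .massstats import kstat_features

logger = logging.getLogger("cleavstat")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    fasta: str
    out_dir: str
    rules: tuple[str, ...] | None = None      # None -> all 16
    max_missed: int = 0
    kstat_mode: str = "signed"
    mass_type: str = "average"
    mode: Literal["features", "train", "predict"] = "features"
    labels_file: str | None = None            # delimited id<TAB>label, for train
    model_file: str | None = None             # JSON model, for predict
    min_length: int = 100
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed <= 5:
            raise ValueError("missed-cleavage ceiling must lie in [0, 5]")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_labels(path) -> dict[str, str]:
    """Read an id -> label map from delimited text (two columns)."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["id", "label"], dtype=str, comment="#")
    return dict(zip(df["id"], df["label"]))


def run_pipeline(config: RunConfig) -> dict:
    """Execute digest -> K_stat -> (train | predict) per the configuration.

    Returns the report dict; artifacts are written under ``config.out_dir``.
    Any stage failure aborts with a stage-named diagnostic and removes the
    partial outputs of this run.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": [],
    }
    try:
        stage = "load"
        records = load_fasta(config.fasta)
        n_loaded = len(records)
        records = prepare_dataset(records, min_length=config.min_length)
        report["stages"].append({"stage": stage, "loaded": n_loaded,
                                 "kept": len(records)})
        if not records:
            raise RuntimeError("no records left after preparation")

        stage = "kstat"
        features = kstat_features(
            records, rules=config.rules, max_missed=config.max_missed,
            mode=config.kstat_mode, mass_type=config.mass_type,
        )
        feat_path = out / "features.csv"
        features.to_csv(feat_path, index_label="id")
        written.append(feat_path)
        report["stages"].append({"stage": stage, "rows": len(features),
                                 "rules": list(features.columns)})

        if config.mode == "train":
            stage = "train"
            if config.labels_file is None:
                raise RuntimeError("training requires a labels file")
            labels = read_labels(config.labels_file)
            common = [i for i in features.index if i in labels]
            y = [labels[i] for i in common]
            model, curves = stepwise_logistic(features.loc[common], y,
                                              kstat_mode=config.kstat_mode)
            model_path = out / "model.json"
            model_path.write_text(model.to_json())
            written.append(model_path)
            report["stages"].append({
                "stage": stage,
                "included_rules": model.included_rules,
                "auc_per_step": [c.auc for c in curves],
                "nagelkerke_r2": model.nagelkerke_r2,
            })
        elif config.mode == "predict":
            stage = "predict"
            if config.model_file is None:
                raise RuntimeError("prediction requires a model file")
            model = BinaryLogisticModel.from_json(Path(config.model_file).read_text())
            decisions = {}
            for pid, row in features.iterrows():
                p, positive = predict_binary(model, row)
                decisions[pid] = {"p": p, "decision": bool(positive)}
            pred_path = out / "predictions.json"
            pred_path.write_text(json.dumps(decisions, indent=1))
            written.append(pred_path)
            report["stages"].append({"stage": stage, "n_predicted": len(decisions),
                                     "p_thr": model.p_threshold})

        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1, default=str))
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# Sequential binary classification
# ---------------------------------------------------------------------------

@dataclass
class DecisionNode:
    """One binary test: a model plus the branch taken on each outcome.

    ``on_positive`` / ``on_negative`` are either another node name or a
    terminal ``"label:<text>"``.
    """

    name: str
    model: BinaryLogisticModel
    on_positive: str
    on_negative: str


@dataclass
class DecisionTree:
    nodes: dict[str, DecisionNode]
    entry: str

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        d = json.loads(text)
        nodes = {}
        for name, spec in d["nodes"].items():
            model = BinaryLogisticModel.from_json(json.dumps(spec["model"]))
            nodes[name] = DecisionNode(name, model,
                                       spec["on_positive"], spec["on_negative"])
        return cls(nodes, d["entry"])

    def to_json(self) -> str:
        return json.dumps({
            "entry": self.entry,
            "nodes": {
                name: {
                    "model": json.loads(node.model.to_json()),
                    "on_positive": node.on_positive,
                    "on_negative": node.on_negative,
                } for name, node in self.nodes.items()
            },
        }, indent=1)


def sequential_classify(feature_row: Mapping[str, float],
                        tree: DecisionTree) -> list[dict]:
    """Apply the binary models of ``tree`` in order, branching on each
    decision, and return the full trace.

    Each trace step records the model name, p, p_thr and the decision; a
    model whose required rules are missing from the row stops the trace with
    a diagnostic entry, preserving the earlier decisions.
    """
    trace: list[dict] = []
    current = tree.entry
    while True:
        node = tree.nodes[current]
        try:
            p, positive = predict_binary(node.model, feature_row)
        except KeyError as exc:
            trace.append({"step": node.name, "error": str(exc)})
            return trace
        branch = node.on_positive if positive else node.on_negative
        trace.append({
            "step": node.name, "p": p, "p_thr": node.model.p_threshold,
            "decision": "positive" if positive else "negative",
            "next": branch,
        })
        if branch.startswith("label:"):
            trace.append({"step": "terminal", "label": branch[len("label:"):]})
            return trace
        current = branch
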