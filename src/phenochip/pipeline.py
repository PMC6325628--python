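"""End-to-end orchestration: one bioreactor run, and whole-study analysis.

``run_assay`` executes chip segmentation → assay segmentation → feature
extraction for one bioreactor and (optionally) writes masks, the feature
row and a provenance sidecar.  ``run_study`` assembles the feature table
across bioreactors and applies the statistics and classification plans.
Reruns with identical config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .chip import ChannelStack, ChipMasks, ChipParams, segment_chip_celldeath, segment_chip_mito, segment_chip_morphometric
from .classification import ClassifierReport, choose_selection_threshold, evaluate_classifier, select_features_by_correlation
from .mitochondria import extract_mito_features, segment_mito_assay
from .morphometrics import extract_morpho_features, segment_morpho_assay
from .records import FeatureRecord, feature_frame
from .skeleton import skeletonize_graph
from .stats import RescueEstimate, bootstrap_rescue, compare_groups
from .viability import extract_viability_features, segment_viability_assay

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "assay", "bioreactor_id", "input_path", "channel_names", "output_dir",
    "seed", "metadata", "chip_params", "write_masks",
}


@dataclass
class RunConfig:
    """Everything one bioreactor run depends on; serialised into provenance."""

    assay: str
    bioreactor_id: str = "br0"
    input_path: str | None = None
    channel_names: list[str] | None = None
    output_dir: str | None = None
    seed: int = 0
    metadata: dict = field(default_factory=dict)
    chip_params: ChipParams | None = None
    write_masks: bool = False

    def __post_init__(self) -> None:
        if self.assay not in ("morpho", "mito", "viability"):
            raise ValueError(f"unknown assay {self.assay!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "chip_params" in raw and raw["chip_params"] is not None:
            raw["chip_params"] = ChipParams(**raw["chip_params"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs are
        written does not affect what is computed)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _segment_chip(stack: ChannelStack, config: RunConfig) -> ChipMasks:
    params = config.chip_params
    if config.assay == "morpho":
        if params is None:
            raise ValueError("morphometric runs need chip_params with rough thresholds")
        return segment_chip_morphometric(stack, params)
    if config.assay == "mito":
        return segment_chip_mito(stack, params)
    return segment_chip_celldeath(stack, params)


def run_assay(config: RunConfig, stack: ChannelStack | None = None) -> FeatureRecord:
    """Segment one bioreactor and extract its feature record.

    `stack` may be passed in memory; otherwise it is read from
    ``config.input_path``.  Inputs are never mutated.  Stage failures are
    re-raised with the stage name and bioreactor id attached.
    """
    if stack is None:
        if config.input_path is None:
            raise ValueError("no stack given and no input_path configured")
        stack = pio.read_stack(config.input_path, config.channel_names)

    stage = "chip segmentation"
    try:
        chip = _segment_chip(stack, config)
        stage = "assay segmentation"
        if config.assay == "morpho":
            masks = segment_morpho_assay(stack, chip)
            stage = "feature extraction"
            graph = skeletonize_graph(masks.th)
            record = extract_morpho_features(
                masks, chip, graph, config.bioreactor_id, config.metadata
            )
        elif config.assay == "mito":
            masks = segment_mito_assay(stack, chip)
            stage = "feature extraction"
            graph = skeletonize_graph(masks.mito)
            record = extract_mito_features(masks, graph, config.bioreactor_id, config.metadata)
        else:
            masks = segment_viability_assay(stack, chip)
            stage = "feature extraction"
            record = extract_viability_features(masks, config.bioreactor_id, config.metadata)
    except Exception as exc:
        raise RuntimeError(
            f"{config.assay} run failed at {stage} (bioreactor {config.bioreactor_id}): {exc}"
        ) from exc

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.write_masks:
            pio.write_mask(out / f"{config.bioreactor_id}_device.tif", chip.device)
            for name in vars(masks):
                pio.write_mask(out / f"{config.bioreactor_id}_{name}.tif", getattr(masks, name))
        prov = {
            "bioreactor_id": config.bioreactor_id,
            "assay": config.assay,
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
        }
        (out / f"{config.bioreactor_id}_provenance.json").write_text(
            json.dumps(prov, indent=2, default=str)
        )
        pd.DataFrame([record.to_row()]).to_csv(
            out / f"{config.bioreactor_id}_features.csv", index=False
        )
    return record


@dataclass
class StudyReport:
    table: pd.DataFrame
    stats: pd.DataFrame | None = None
    rescues: list[RescueEstimate] = field(default_factory=list)
    classifier: ClassifierReport | None = None
    selection_threshold: float | None = None


def run_study(
    records: list[FeatureRecord],
    stats_plan: dict | None = None,
    rescue_plan: dict | None = None,
    classify_plan: dict | None = None,
    seed: int = 0,
) -> StudyReport:
    """Aggregate feature rows and run the planned statistics/classification.

    stats_plan:    {"features": [...], "group_col": str, "pairs": [...],
                    "m_adjust": int}
    rescue_plan:   {"feature": str, "wt": (col, level), "mut": ..,
                    "treated": .., "iterations": int, "k": int}
    classify_plan: {"features": [...], "label_col": str, "positive": str,
                    "select_thresholds": [...], "repeats": int, "folds": int,
                    "c_grid": [...], "gamma_grid": [...]}
    """
    table = feature_frame(records)
    report = StudyReport(table=table)

    if stats_plan:
        group_col = stats_plan["group_col"]
        if table[group_col].nunique() < 2:
            logger.warning("single-group plan: statistics skipped")
        else:
            rows = []
            for feat in stats_plan["features"]:
                for r in compare_groups(
                    table, feat, group_col,
                    post_hoc_pairs=stats_plan.get("pairs"),
                    m_adjust=stats_plan.get("m_adjust"),
                ):
                    rows.append(dataclasses.asdict(r))
            report.stats = pd.DataFrame(rows)

    if rescue_plan:
        feat = rescue_plan["feature"]

        def pick(sel):
            col, level = sel
            return table.loc[table[col] == level, feat].dropna().to_numpy()

        wt, mut, tr = (pick(rescue_plan[k]) for k in ("wt", "mut", "treated"))
        if wt.size and mut.size and np.mean(wt) == np.mean(mut):
            logger.warning("rescue undefined: identical group means; skipped")
        else:
            report.rescues.append(
                bootstrap_rescue(
                    wt, mut, tr,
                    iterations=rescue_plan.get("iterations", 100_000),
                    k=rescue_plan.get("k", 10),
                    seed=seed, feature=feat,
                )
            )

    if classify_plan:
        feats = classify_plan["features"]
        sub = table[feats]
        labels = table[classify_plan["label_col"]]
        kwargs = {
            k: classify_plan[k]
            for k in ("repeats", "folds", "c_grid", "gamma_grid")
            if k in classify_plan
        }
        thresholds = classify_plan.get("select_thresholds")
        if thresholds:
            best, reports = choose_selection_threshold(
                sub, labels, classify_plan["positive"],
                candidate_thresholds=thresholds, seed=seed, **kwargs,
            )
            report.selection_threshold = best
            report.classifier = reports[best]
        else:
            report.classifier = evaluate_classifier(
                sub, labels, classify_plan["positive"], seed=seed, **kwargs
            )
    return report
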