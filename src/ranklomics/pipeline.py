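"""End-to-end orchestration: cohort directory -> features -> classification report.

Cohort directory layout: ``<id>_img.png`` + ``<id>_mask.png`` per case (DICOM
accepted with the same naming and a .dcm suffix) plus a ``labels.csv`` with
columns case_id, label.  ``run_extract`` writes one feature row per case,
logging and skipping unreadable cases; ``run_classify`` runs stepwise
selection + LOO per feature panel and assembles the metric panel, per-feature
significance table and chi-squared comparisons between panels, echoing the
full configuration for byte-level replay.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ClassifierSpec,
    compare_performance_chi2,
    confusion_metrics,
    feature_significance,
    loo_evaluate,
    nested_loo_evaluate,
    stepwise_backward_select,
)
from .core import CaseFeatureRow, Dataset
from .errors import RanklomicsError, SchemaError
from .io import load_case, read_feature_table, write_feature_table
from .texture import extract_case_features, panel_columns

logger = logging.getLogger(__name__)

RANKLET_SOURCES = ("ranklet_vertical", "ranklet_horizontal", "ranklet_diagonal")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with study defaults.

    resolution 4, d = 1 and the four averaged directions are the standard
    settings of this pipeline; gray-level counts, the classifier family and
    the 0.5 threshold are documented package defaults.
    """

    resolution: int = 4
    stride: int | None = None
    levels_raw: int = 32
    levels_ranklet: int = 8
    distance: int = 1
    symmetric: bool = True
    classifier: str = "logistic"
    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_cost: float = 1.0
    threshold: float = 0.5
    standardize: bool = True
    nested_validation: bool = False
    seed: int = 0

    def spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            kind=self.classifier,
            k=self.knn_k,
            kernel=self.svm_kernel,
            cost=self.svm_cost,
            threshold=self.threshold,
            standardize=self.standardize,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


#: Feature panels evaluated by run_classify: four GLCM panels and two GLRLM
#: panels (the ranklet GLRLM panel pools the three orientations).
def classification_panels() -> dict[str, list[str]]:
    panels = {
        "raw_glcm": panel_columns("raw", "glcm14"),
        "ranklet_vertical_glcm": panel_columns("ranklet_vertical", "glcm14"),
        "ranklet_horizontal_glcm": panel_columns("ranklet_horizontal", "glcm14"),
        "ranklet_diagonal_glcm": panel_columns("ranklet_diagonal", "glcm14"),
        "raw_glrlm": panel_columns("raw", "glrlm11"),
        "ranklet_glrlm": [
            c for s in RANKLET_SOURCES for c in panel_columns(s, "glrlm11")
        ],
    }
    return panels


def _find_cases(cohort_dir: Path) -> list[tuple[str, Path, Path, int | None]]:
    labels: dict[str, int] = {}
    labels_path = cohort_dir / "labels.csv"
    if labels_path.exists():
        frame = pd.read_csv(labels_path)
        labels = dict(zip(frame["case_id"].astype(str), frame["label"].astype(int)))
    found = []
    for img_path in sorted(cohort_dir.glob("*_img.*")):
        case_id = img_path.name.rsplit("_img.", 1)[0]
        masks = sorted(cohort_dir.glob(f"{case_id}_mask.*"))
        if not masks:
            logger.warning("no mask found for case %s; skipped", case_id)
            continue
        found.append((case_id, img_path, masks[0], labels.get(case_id)))
    return found


def run_extract(
    cohort_dir: str | Path, config: RunConfig, out_csv: str | Path | None = None
) -> list[CaseFeatureRow]:
    """Extract all feature panels for every readable case in a cohort directory."""
    cohort_dir = Path(cohort_dir)
    entries = _find_cases(cohort_dir)
    rows: list[CaseFeatureRow] = []
    n_skipped = 0
    for case_id, img_path, mask_path, label in entries:
        try:
            case = load_case(img_path, mask_path, case_id=case_id, label=label)
            rows.append(
                extract_case_features(
                    case,
                    resolution=config.resolution,
                    stride=config.stride,
                    levels_raw=config.levels_raw,
                    levels_ranklet=config.levels_ranklet,
                    d=config.distance,
                    symmetric=config.symmetric,
                )
            )
            logger.info("extracted %s (%d features)", case_id, len(rows[-1].features))
        except (RanklomicsError, OSError, ValueError) as exc:
            n_skipped += 1
            logger.warning("case %s skipped: %s", case_id, exc)
    if not rows:
        raise RanklomicsError(f"no readable cases in {cohort_dir}")
    if n_skipped:
        logger.warning("%d of %d cases skipped", n_skipped, len(entries))
    if out_csv is not None:
        write_feature_table(rows, out_csv)
    return rows


def _metrics_dict(m) -> dict:
    return {
        "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
        "accuracy": m.accuracy, "sensitivity": m.sensitivity,
        "specificity": m.specificity, "ppv": m.ppv, "npv": m.npv,
    }


def run_classify(features: str | Path | Dataset, config: RunConfig) -> dict:
    """Stepwise selection + LOO + metrics + statistics for every panel."""
    if isinstance(features, (str, Path)):
        data = read_feature_table(features)
    else:
        data = features
    if len(np.unique(data.labels)) < 2:
        raise RanklomicsError("labels must contain both classes")
    spec = config.spec()
    report: dict = {"config": config.to_dict(), "panels": {}}
    metrics_by_panel = {}
    for panel_name, columns in classification_panels().items():
        missing = [c for c in columns if c not in data.features.columns]
        if missing:
            logger.warning("panel %s missing columns; skipped: %s", panel_name, missing[:3])
            continue
        panel_data = data.subset(columns)
        if config.nested_validation:
            result = nested_loo_evaluate(panel_data, spec)
        else:
            result = stepwise_backward_select(panel_data, spec)
        metrics = confusion_metrics(result, data.labels)
        metrics_by_panel[panel_name] = metrics
        significance = {}
        n_tests = len(result.selected_features)
        for feat in result.selected_features:
            rep = feature_significance(data.features[feat].to_numpy(), data.labels)
            significance[feat] = {
                "test": rep.test_name,
                "statistic": rep.statistic,
                "p_value": rep.p_value,
                "p_bonferroni": min(1.0, rep.p_value * n_tests),
            }
        report["panels"][panel_name] = {
            "selected_features": result.selected_features,
            "trace": result.trace,
            "loo_error": result.error_rate,
            "probabilities": dict(zip(data.case_ids, map(float, result.probabilities))),
            "metrics": _metrics_dict(metrics),
            "significance": significance,
        }
    comparisons = {}
    baseline = metrics_by_panel.get("raw_glcm")
    if baseline is not None:
        for panel_name, metrics in metrics_by_panel.items():
            if panel_name == "raw_glcm":
                continue
            chi2, p = compare_performance_chi2(metrics, baseline)
            comparisons[f"{panel_name}_vs_raw_glcm"] = {"chi2": chi2, "p_value": p}
    report["panel_comparisons"] = comparisons
    return report


def loo_single_panel(
    data: Dataset, panel: str, config: RunConfig
) -> tuple[dict, "object"]:
    """Stepwise + LOO on one named panel; returns (summary dict, LooResult)."""
    columns = classification_panels()[panel]
    result = stepwise_backward_select(data.subset(columns), config.spec())
    metrics = confusion_metrics(result, data.labels)
    return _metrics_dict(metrics), result
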