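"""Sample-level decision model and the end-to-end analysis pipeline.

A trained cell-level classifier turns each sample into a predicted percentage
of critically sickled cells. The sample-level decision rule calls a sample
SCD when that percentage strictly exceeds a lower bound (default 8%); the
8–25% range additionally serves as a severity band, reported as the position
of the sample's percentage within it.

:func:`run_pipeline` composes the whole chain: simulate -> extract features
-> QC -> selective-search refinement -> train (SEL and ALL variants) ->
evaluate every test sample -> decide.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, morphometry, refine, synthgen
from .exceptions import ConfigurationError, PipelineStageError, UnsegmentableError

__all__ = [
    "DecisionThresholds",
    "SampleReport",
    "decide_sample",
    "make_sample_report",
    "PipelineResult",
    "run_pipeline",
]

logger = logging.getLogger("holocyte")


@dataclass(frozen=True)
class DecisionThresholds:
    """Decision-model bounds on the predicted diseased-cell percentage."""

    lower_bound_pct: float = 8.0
    upper_band_pct: float = 25.0

    def __post_init__(self):
        if not (0.0 < self.lower_bound_pct < self.upper_band_pct < 100.0):
            raise ConfigurationError("require 0 < lower < upper < 100")


@dataclass
class SampleReport:
    """Per-sample prediction plus the sample-level call."""

    sample_id: str
    pct_normal: float
    pct_scd: float
    n_cells: int
    call: str  # "NORMAL" | "SCD"
    severity_band_position: float

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "pct_normal": self.pct_normal,
            "pct_scd": self.pct_scd,
            "n_cells": self.n_cells,
            "call": self.call,
            "severity_band_position": self.severity_band_position,
        }


def decide_sample(pct_scd: float, thresholds: DecisionThresholds | None = None) -> str:
    """Call a sample SCD iff its predicted diseased-cell percentage strictly
    exceeds the lower bound (default: more than 8%)."""
    thresholds = thresholds or DecisionThresholds()
    if not (0.0 <= pct_scd <= 100.0):
        raise ConfigurationError(f"pct_scd out of range: {pct_scd}")
    return "SCD" if pct_scd > thresholds.lower_bound_pct else "NORMAL"


def make_sample_report(
    pred: classify.SamplePrediction, thresholds: DecisionThresholds | None = None
) -> SampleReport:
    thresholds = thresholds or DecisionThresholds()
    call = decide_sample(pred.pct_scd, thresholds)
    band = (pred.pct_scd - thresholds.lower_bound_pct) / (
        thresholds.upper_band_pct - thresholds.lower_bound_pct
    )
    return SampleReport(
        sample_id=pred.sample_id,
        pct_normal=pred.pct_normal,
        pct_scd=pred.pct_scd,
        n_cells=pred.n_cells,
        call=call,
        severity_band_position=max(0.0, band),
    )


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    features: pd.DataFrame  # post-QC feature table (train + test cells)
    qc_excluded: pd.DataFrame
    criteria: list
    refined: refine.RefinedSet
    models: dict  # variant name -> (TrainedModel, MetricsReport)
    sample_reports: dict  # variant name -> list[SampleReport]
    counts: dict
    summary: pd.DataFrame
    crops: np.ndarray | None = None  # CNN inputs aligned with the pre-QC row index


def _subsample_balanced(
    table: pd.DataFrame, per_class: int | None, seed: int
) -> pd.DataFrame:
    if per_class is None:
        return table
    rng = np.random.default_rng(seed)
    parts = []
    for label, grp in table.groupby("label"):
        k = min(per_class, len(grp))
        parts.append(grp.iloc[np.sort(rng.choice(len(grp), size=k, replace=False))])
    return pd.concat(parts)


def run_pipeline(
    study: synthgen.StudyConfig | None = None,
    refine_config: refine.RefineConfig | None = None,
    train_config: classify.TrainConfig | None = None,
    thresholds: DecisionThresholds | None = None,
    models: tuple[str, ...] = ("LR",),
    all_train_per_class: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis chain on a (synthetic) study.

    Parameters
    ----------
    study
        Study roster; defaults to the ~50k-cell default study.
    models
        Model families to train: ``("LR",)`` or ``("LR", "CNN")``. Image
        crops are retained in memory only when the CNN is requested.
    all_train_per_class
        Optional cap on per-class training size for the ALL variants
        (mirrors randomly subsampled unrefined training pools).
    out_dir
        If given, all artifacts (criteria, refined set, metrics, per-sample
        summary, QC report) are written there.
    """
    study = study or synthgen.default_study_config()
    refine_config = refine_config or refine.RefineConfig()
    train_config = train_config or classify.TrainConfig()
    thresholds = thresholds or DecisionThresholds()
    want_cnn = "CNN" in models
    wavelength = study.imaging.wavelength_nm

    # -- stage 1: simulate + extract features (streaming) -------------------
    rows: list[dict] = []
    crops: list[np.ndarray] = []
    n_simulated = 0
    n_unsegmentable = 0
    try:
        for pop in study.all_samples:
            logger.info("simulating sample %s (%d cells)", pop.sample_id, pop.n_cells)
            for img, rec in synthgen.iter_sample_cells(pop, study.imaging):
                n_simulated += 1
                try:
                    feats = morphometry.compute_features(img, wavelength)
                except UnsegmentableError:
                    n_unsegmentable += 1
                    continue
                row = rec.as_dict()
                row.update(feats)
                rows.append(row)
                if want_cnn:
                    crops.append(
                        classify.prepare_cnn_inputs([img], train_config)[0].astype(np.float32)
                    )
    except Exception as e:  # noqa: BLE001 - rewrap with stage context
        raise PipelineStageError("simulate/features", str(e)) from e
    table = pd.DataFrame(rows).reset_index(drop=True)
    crop_arr = np.stack(crops) if want_cnn else None

    # -- stage 2: QC --------------------------------------------------------
    try:
        kept, excluded = morphometry.qc_filter(table)
    except Exception as e:
        raise PipelineStageError("qc", str(e)) from e
    counts = {
        "cells_simulated": n_simulated,
        "cells_unsegmentable": n_unsegmentable,
        "cells_qc_excluded": len(excluded),
        "cells_kept": len(kept),
    }
    assert counts["cells_simulated"] == (
        counts["cells_kept"] + counts["cells_qc_excluded"] + counts["cells_unsegmentable"]
    )
    logger.info("QC: %s", counts)

    train_ids = {p.sample_id for p in study.train_scd} | {p.sample_id for p in study.train_nor}
    train_tab = kept[kept["sample_id"].isin(train_ids)]
    test_tab = kept[~kept["sample_id"].isin(train_ids)]

    # -- stage 3: refinement -------------------------------------------------
    try:
        criteria, refined = refine.refine_training_set(train_tab, refine_config)
    except Exception as e:
        raise PipelineStageError("refine", str(e)) from e
    logger.info(
        "refinement: %d criteria, %d SCD cells selected%s",
        len(criteria),
        refined.size,
        f" ({refined.warning})" if refined.warning else "",
    )

    # -- stage 4: training ---------------------------------------------------
    sel_idx = refined.scd_indices.append(refined.matched_nor_indices)
    all_tab = _subsample_balanced(train_tab, all_train_per_class, train_config.seed)
    sel_tab = train_tab.loc[sel_idx]
    fitted: dict = {}
    try:
        for family in models:
            for variant, tab in (("ALL", all_tab), ("SEL", sel_tab)):
                name = f"{family}-{variant}"
                if family == "LR":
                    model, rep = classify.train_logistic(
                        tab, tab["label"].to_numpy(), train_config
                    )
                elif family == "CNN":
                    model, rep = classify.train_cnn(
                        crop_arr[tab.index.to_numpy()],
                        tab["label"].to_numpy(),
                        train_config,
                    )
                else:
                    raise ConfigurationError(f"unknown model family {family!r}")
                fitted[name] = (model, rep)
                logger.info("%s: acc %.2f%% auc %.4f", name, rep.accuracy_mean, rep.auc)
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("train", str(e)) from e

    # -- stage 5: evaluate test samples + decide -----------------------------
    sample_reports: dict = {}
    summary_rows = []
    try:
        for name, (model, _rep) in fitted.items():
            reports = []
            for pop in study.test_samples:
                sub = test_tab[test_tab["sample_id"] == pop.sample_id]
                data = sub if model.kind == "LR" else crop_arr[sub.index.to_numpy()]
                pred = classify.evaluate_sample(
                    model, data, sample_id=pop.sample_id, config=train_config
                )
                rep = make_sample_report(pred, thresholds)
                reports.append(rep)
                summary_rows.append(
                    {
                        "model": name,
                        "sample_id": pop.sample_id,
                        "type": pop.label,
                        "pct_normal": round(rep.pct_normal, 2),
                        "pct_scd": round(rep.pct_scd, 2),
                        "n_cells": rep.n_cells,
                        "call": rep.call,
                    }
                )
            sample_reports[name] = reports
    except Exception as e:
        raise PipelineStageError("evaluate", str(e)) from e

    summary = pd.DataFrame(summary_rows)
    result = PipelineResult(
        features=kept,
        qc_excluded=excluded,
        criteria=criteria,
        refined=refined,
        models=fitted,
        sample_reports=sample_reports,
        counts=counts,
        summary=summary,
        crops=crop_arr,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir), refine_config)
    return result


def _write_bundle(result: PipelineResult, out: Path, refine_config: refine.RefineConfig):
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary.to_dict(orient="records"), fh, indent=2)
    with open(out / "criteria.json", "w") as fh:
        json.dump(
            [
                {
                    "parameter": c.parameter,
                    "direction": c.direction,
                    "threshold": c.threshold,
                    "achieved_ratio": c.achieved_ratio,
                    "n_scd_tail": c.n_scd_tail,
                    "n_nor_tail": c.n_nor_tail,
                }
                for c in result.criteria
            ],
            fh,
            indent=2,
        )
    refined_rows = [
        {
            "cell_id": result.features.loc[i, "cell_id"],
            "role": "scd",
            "criteria": ";".join(result.refined.provenance.get(i, [])),
        }
        for i in result.refined.scd_indices
    ] + [
        {"cell_id": result.features.loc[i, "cell_id"], "role": "matched_normal", "criteria": ""}
        for i in result.refined.matched_nor_indices
    ]
    pd.DataFrame(refined_rows).to_csv(out / "refined_set.csv", index=False)
    metrics = {
        name: rep.as_dict() for name, (_m, rep) in result.models.items()
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    qc_counts = (
        result.qc_excluded["excluded_by"].value_counts().to_dict()
        if len(result.qc_excluded)
        else {}
    )
    with open(out / "qc_report.json", "w") as fh:
        json.dump({"counts": result.counts, "per_rule": qc_counts,
                   "balancing_seed": refine_config.seed}, fh, indent=2)
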