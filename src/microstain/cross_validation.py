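"""Grouped stratified repeated cross-validation of the two-stage classifier.

Patients are partitioned into k stratified folds (all tiles of a patient stay
together), the plan is repeated R times with fresh shuffles, and within every
(repeat, fold) the tile CNN is trained on training-fold tiles (validation-fold
tiles serving as its model-selection set), its predictions are aggregated into
slide features, and the patient-level forest is trained on training-fold
slides only and evaluated on the validation fold via repeated fits. Fold
sensitivities/specificities are combined within a repeat as weighted means
(weights = validation-fold class sizes), AUCs as plain means; repeat-level
values are then averaged, with the across-repeat sample SD reported for the
AUC.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from . import slide_level, tile_classifier
from .diag_stats import round_half_away
from .synthetic_data import (ABMR_PARAMS, OTHER_PARAMS, Label, SlideRecord,
                             generate_cohort)
from .tile_classifier import BackboneSpec, TrainingSchedule
from .tiling import tile_slide

__all__ = [
    "FoldPlan",
    "FoldEntry",
    "CVReport",
    "make_folds",
    "run_cv",
    "summarize",
    "run_synthetic_experiment",
]


@dataclass
class FoldPlan:
    """Patient-to-fold assignments for every repeat (1-based indices)."""

    k: int
    repeats: int
    seed: int
    labels: dict[str, str]                      # patient_id -> class label
    assignments: dict[int, dict[str, int]]      # repeat -> {patient_id: fold}

    def validate(self) -> None:
        """Partition property: every patient in exactly one fold per repeat."""
        pids = set(self.labels)
        for r, assign in self.assignments.items():
            if set(assign) != pids:
                raise ValueError(f"repeat {r}: fold assignment is not a "
                                 "partition of the cohort")
            if not set(assign.values()) <= set(range(1, self.k + 1)):
                raise ValueError(f"repeat {r}: fold index out of range")

    def fold_patients(self, repeat: int, fold: int) -> list[str]:
        return [p for p, f in self.assignments[repeat].items() if f == fold]

    def class_counts(self, repeat: int) -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {f: {} for f in range(1, self.k + 1)}
        for pid, f in self.assignments[repeat].items():
            lab = self.labels[pid]
            out[f][lab] = out[f].get(lab, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": p, "repeat": r, "fold": f}
                for r, assign in self.assignments.items()
                for p, f in assign.items()]
        return pd.DataFrame(rows)


def make_folds(patient_ids, labels, k: int = 3, repeats: int = 5,
               seed: int = 0) -> FoldPlan:
    """Stratified (by label), grouped (by patient) repeated k-fold plan.

    Deterministic for a fixed seed; each repeat reshuffles. A class with
    fewer than k members cannot be spread over k folds and is rejected.
    """
    patient_ids = [str(p) for p in patient_ids]
    labels = [str(getattr(l, "value", l)) for l in labels]
    if len(set(patient_ids)) != len(patient_ids):
        raise ValueError("duplicate patient ids")
    for cls in sorted(set(labels)):
        n_cls = labels.count(cls)
        if n_cls < k:
            raise ValueError(f"class {cls!r} has only {n_cls} patients; "
                             f"cannot build {k} folds")
    X = np.zeros((len(patient_ids), 1))
    y = np.asarray(labels)
    groups = np.asarray(patient_ids)
    assignments: dict[int, dict[str, int]] = {}
    for r in range(1, repeats + 1):
        sgkf = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=seed + r - 1)
        assign: dict[str, int] = {}
        for fold_idx, (_, val_idx) in enumerate(sgkf.split(X, y, groups), start=1):
            for i in val_idx:
                assign[patient_ids[i]] = fold_idx
        assignments[r] = assign
    plan = FoldPlan(k=k, repeats=repeats, seed=seed,
                    labels=dict(zip(patient_ids, labels)),
                    assignments=assignments)
    plan.validate()
    return plan


@dataclass
class FoldEntry:
    repeat: int
    fold: int
    tile_auc: float
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    n_abmr_val: int
    n_other_val: int


def _weighted_mean(values, weights) -> float:
    values = np.asarray(values, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    return float(np.sum(values * weights) / np.sum(weights))


@dataclass
class CVReport:
    entries: list[FoldEntry] = field(default_factory=list)

    def repeat_summary(self) -> pd.DataFrame:
        """One row per repeat: mean AUC over folds, class-size-weighted Se/Sp."""
        rows = []
        for r in sorted({e.repeat for e in self.entries}):
            es = [e for e in self.entries if e.repeat == r]
            rows.append({
                "repeat": r,
                "auc": float(np.mean([e.auc for e in es])),
                "tile_auc": float(np.mean([e.tile_auc for e in es])),
                "threshold": float(np.mean([e.threshold for e in es])),
                "sensitivity": _weighted_mean([e.sensitivity for e in es],
                                              [e.n_abmr_val for e in es]),
                "specificity": _weighted_mean([e.specificity for e in es],
                                              [e.n_other_val for e in es]),
            })
        return pd.DataFrame(rows)

    def overall(self) -> dict:
        rs = self.repeat_summary()
        aucs = rs["auc"].to_numpy()
        return {
            "auc_mean": float(aucs.mean()),
            "auc_sd": float(np.std(aucs, ddof=1)) if aucs.size > 1 else 0.0,
            "tile_auc_mean": float(rs["tile_auc"].mean()),
            "sensitivity_mean": float(rs["sensitivity"].mean()),
            "specificity_mean": float(rs["specificity"].mean()),
            "threshold_mean": float(rs["threshold"].mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])

    def to_json(self, path=None) -> str:
        payload = {"folds": [asdict(e) for e in self.entries],
                   "repeats": self.repeat_summary().to_dict(orient="records"),
                   "overall": self.overall()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class _CNNFactory:
    """Default model-1 trainer: builds and trains the small CNN per fold."""

    def __init__(self, backbone: BackboneSpec, schedule: TrainingSchedule):
        self.backbone = backbone
        self.schedule = schedule

    def __call__(self, x_train, y_train, x_val, y_val, seed):
        model = tile_classifier.build_model(self.backbone, seed=seed)
        tile_classifier.train(model, x_train, y_train, x_val, y_val,
                              schedule=self.schedule, seed=seed)
        return model


def run_cv(slides: list[SlideRecord], plan: FoldPlan, *,
           backbone: BackboneSpec = BackboneSpec(),
           schedule: TrainingSchedule | None = None,
           tile_size: int = 64, min_tissue_fraction: float = 0.5,
           pool_size: int = 10, stride: int = 5,
           n_trees: int = 100, n_iter: int = 50, seed: int = 0,
           model1_factory=None) -> CVReport:
    """Run the full two-stage pipeline under a maintained split.

    For each (repeat, fold): model 1 is trained on training-fold tiles with
    the validation-fold tiles as its model-selection set, its predictions for
    every slide are aggregated into the 12 features, and model 2 is trained on
    training-fold features only and evaluated on the validation fold with
    repeated forest fits. A patient appearing on both sides of a split is a
    hard error. ``model1_factory(x_train, y_train, x_val, y_val, seed)`` may
    replace the CNN trainer (it must return an object usable by
    ``predict_tiles``/``predict_array`` or expose ``predict_tiles``).
    """
    plan.validate()
    schedule = schedule or TrainingSchedule.from_scratch()
    by_pid = {s.patient_id: s for s in slides}
    if set(by_pid) != set(plan.labels):
        raise ValueError("fold plan does not cover exactly the supplied slides")
    factory = model1_factory or _CNNFactory(backbone, schedule)

    tilesets = {pid: tile_slide(s, tile_size, min_tissue_fraction)
                for pid, s in by_pid.items()}
    arrays = {pid: tile_classifier.tiles_to_array(ts, backbone.input_size)
              for pid, ts in tilesets.items()}
    y_slide = {pid: int(by_pid[pid].label is Label.ABMR) for pid in by_pid}

    report = CVReport()
    for r in sorted(plan.assignments):
        for f in range(1, plan.k + 1):
            val_pids = sorted(plan.fold_patients(r, f))
            train_pids = sorted(set(by_pid) - set(val_pids))
            if set(val_pids) & set(train_pids):
                raise RuntimeError("leakage: patient present in both train "
                                   "and validation sets")
            fold_seed = (seed + 9973 * r + 101 * f) % (2**31 - 1)

            x_tr = np.concatenate([arrays[p] for p in train_pids])
            y_tr = np.concatenate([np.full(len(arrays[p]), y_slide[p])
                                   for p in train_pids])
            x_va = np.concatenate([arrays[p] for p in val_pids])
            y_va = np.concatenate([np.full(len(arrays[p]), y_slide[p])
                                   for p in val_pids])
            scorer = factory(x_tr, y_tr, x_va, y_va, fold_seed)

            series = {}
            for pid in by_pid:
                if hasattr(scorer, "predict_tiles"):
                    series[pid] = scorer.predict_tiles(tilesets[pid])
                else:
                    probs = tile_classifier.predict_array(scorer, arrays[pid])
                    series[pid] = tile_classifier.TilePredictionSeries(
                        pid, tilesets[pid].marker, probs)
            val_tile_scores = np.concatenate(
                [series[p].probabilities for p in val_pids])
            tile_auc = float(roc_auc_score(y_va, val_tile_scores))

            feats = {pid: slide_level.aggregate(series[pid], pool_size,
                                                stride).as_array()
                     for pid in by_pid}
            ev = slide_level.evaluate_repeated(
                np.stack([feats[p] for p in train_pids]),
                [y_slide[p] for p in train_pids],
                np.stack([feats[p] for p in val_pids]),
                [y_slide[p] for p in val_pids],
                n_iter=n_iter, n_trees=n_trees, seed=fold_seed)

            n_abmr = sum(y_slide[p] for p in val_pids)
            report.entries.append(FoldEntry(
                repeat=r, fold=f, tile_auc=tile_auc, auc=ev.mean_auc,
                threshold=ev.mean_threshold, sensitivity=ev.mean_sensitivity,
                specificity=ev.mean_specificity, n_abmr_val=n_abmr,
                n_other_val=len(val_pids) - n_abmr))
    return report


def summarize(report: CVReport) -> str:
    """Printable 'AUC mean (SD), Se, Sp' line (AUC to 2 decimals, Se/Sp to
    integer percent, half-away-from-zero)."""
    o = report.overall()
    return (f"AUC {o['auc_mean']:.2f} ({o['auc_sd']:.2f}), "
            f"Se {round_half_away(o['sensitivity_mean'])}%, "
            f"Sp {round_half_away(o['specificity_mean'])}%")


def run_synthetic_experiment(n_abmr: int = 8, n_other: int = 16,
                             k: int = 3, repeats: int = 2, seed: int = 0,
                             null: bool = False, height: int = 256,
                             width: int = 256, tile_size: int = 64,
                             n_iter: int = 50,
                             backbone: BackboneSpec = BackboneSpec(),
                             schedule: TrainingSchedule | None = None,
                             model1_factory=None) -> CVReport:
    """End-to-end demonstration run on a generated cohort.

    With ``null=True`` both classes are drawn from the identical staining
    parameter set, removing the class effect: the pipeline should then score
    at chance level.
    """
    params = ({Label.ABMR: ABMR_PARAMS, Label.OTHER: ABMR_PARAMS} if null
              else {Label.ABMR: ABMR_PARAMS, Label.OTHER: OTHER_PARAMS})
    cohort = generate_cohort(n_abmr, n_other, params_by_class=params,
                             height=height, width=width, seed=seed)
    plan = make_folds([s.patient_id for s in cohort],
                      [s.label for s in cohort], k=k, repeats=repeats,
                      seed=seed + 1)
    return run_cv(cohort, plan, backbone=backbone, schedule=schedule,
                  tile_size=tile_size, n_iter=n_iter, seed=seed + 2,
                  model1_factory=model1_factory)
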