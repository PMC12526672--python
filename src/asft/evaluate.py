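"""Classification metrics and the two cross-validation protocols.

Cross-clip: samples (2 s feature vectors) are shuffled and split into
stratified folds, so one subject's data can sit in both train and validation.
Cross-subject: subjects are partitioned into subject-disjoint folds and the
partition is repeated with fresh randomisation, measuring generalisation to
unseen people; 5 repetitions × 4 folds → 20 fold-level evaluations.

By default any feature/channel selection is refit inside each training fold
(no selection leakage); ``paper_mode=True`` instead fits the selection once on
all data before splitting, reproducing the global-selection protocol.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import fttransformer as ftt
from .io import FeatureTable
from .select import Selection, SelectionConfig, fit_selection

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              positive: int = 1) -> ConfusionCounts:
    """Confusion counts with class 1 (fatigue) as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos, neg = y_true == positive, y_true != positive
    return ConfusionCounts(
        TP=int((pos & (y_pred == positive)).sum()),
        TN=int((neg & (y_pred != positive)).sum()),
        FP=int((neg & (y_pred == positive)).sum()),
        FN=int((pos & (y_pred != positive)).sum()),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1; zero denominators give 0 with a warning."""
    if counts.n < 1:
        raise ValueError("empty confusion counts")

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.warning("%s has a zero denominator; reporting 0", name)
            return 0.0
        return num / den

    acc = (counts.TP + counts.TN) / counts.n
    prec = safe(counts.TP, counts.TP + counts.FP, "precision")
    rec = safe(counts.TP, counts.TP + counts.FN, "recall")
    f1 = safe(2 * prec * rec, prec + rec, "F1")
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class FoldResult:
    rep: int
    fold: int
    metrics: dict[str, float]
    n_val: int
    val_subjects: tuple[str, ...]


@dataclass
class EvalReport:
    scheme: str  # "cross_clip" | "cross_subject"
    folds: list[FoldResult]
    seed: int
    wall_clock_s: float = 0.0
    selection_mode: str = "none"
    paper_mode: bool = False

    def aggregate(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in METRIC_NAMES:
            vals = np.array([f.metrics[name] for f in self.folds])
            out[name] = {"mean": float(vals.mean()), "std": float(vals.std())}
        return out

    @property
    def mean_accuracy(self) -> float:
        return self.aggregate()["accuracy"]["mean"]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "selection_mode": self.selection_mode,
            "paper_mode": self.paper_mode,
            "aggregate": self.aggregate(),
            "folds": [{"rep": f.rep, "fold": f.fold, "n_val": f.n_val,
                       "val_subjects": list(f.val_subjects), **f.metrics}
                      for f in self.folds],
            "wall_clock_s": self.wall_clock_s,
        }

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [f"{self.scheme} ({len(self.folds)} folds, "
                 f"selection={self.selection_mode})"]
        for name in METRIC_NAMES:
            lines.append(f"  {name:<9} {agg[name]['mean']:6.4f} "
                         f"± {agg[name]['std']:.4f}")
        return "\n".join(lines)


@dataclass
class EvalConfig:
    """Everything one CV run needs: model, selection, folds, seeding."""

    model: ftt.FTTConfig = field(default_factory=ftt.FTTConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_folds: int = 4
    n_reps: int = 5  # cross-subject only
    paper_mode: bool = False
    seed: int = 0


def _fit_eval_fold(train: FeatureTable, val: FeatureTable,
                   cfg: EvalConfig, selection: Selection | None,
                   fold_seed: int) -> dict[str, float]:
    if selection is None and cfg.selection.mode != "none":
        selection = fit_selection(
            train, replace(cfg.selection, seed=fold_seed))
    if selection is not None and cfg.selection.mode != "none":
        train, val = selection.apply(train), selection.apply(val)
    model_cfg = replace(cfg.model, seed=fold_seed)
    fitted = ftt.fit(train, cfg=model_cfg)
    y_pred = fitted.predict(val.X)
    return metrics(confusion(ftt.labels_from_table(val), y_pred))


def _check_partition(n: int, fold_indices: Sequence[np.ndarray]) -> None:
    flat = np.concatenate(fold_indices)
    if len(flat) != n or len(np.unique(flat)) != n:
        raise AssertionError("validation folds do not partition the samples")


def cross_clip_cv(table: FeatureTable, cfg: EvalConfig) -> EvalReport:
    """Stratified n-fold CV over individual samples (clips)."""
    t0 = time.perf_counter()
    y = ftt.labels_from_table(table)
    if np.bincount(y).min() < cfg.n_folds:
        raise ValueError("not enough samples per class for the fold count")
    global_sel = (fit_selection(table, cfg.selection)
                  if cfg.paper_mode and cfg.selection.mode != "none" else None)
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=cfg.seed)
    folds, val_sets = [], []
    for i, (tr, va) in enumerate(skf.split(table.X, y)):
        val_sets.append(va)
        m = _fit_eval_fold(table.take(tr), table.take(va), cfg, global_sel,
                           fold_seed=cfg.seed * 1000 + i)
        subjects = tuple(sorted(set(table.meta["subject_id"].iloc[va])))
        folds.append(FoldResult(rep=0, fold=i, metrics=m, n_val=len(va),
                                val_subjects=subjects))
    _check_partition(table.n_samples, val_sets)
    return EvalReport(scheme="cross_clip", folds=folds, seed=cfg.seed,
                      wall_clock_s=time.perf_counter() - t0,
                      selection_mode=cfg.selection.mode,
                      paper_mode=cfg.paper_mode)


def subject_folds(subjects: Sequence[str], n_folds: int,
                  rng: np.random.Generator) -> list[list[str]]:
    """Random near-equal subject-disjoint partition."""
    subjects = np.asarray(sorted(set(subjects)))
    if len(subjects) < n_folds:
        raise ValueError("fewer subjects than folds")
    perm = rng.permutation(len(subjects))
    return [list(subjects[chunk]) for chunk in np.array_split(perm, n_folds)]


def cross_subject_cv(table: FeatureTable, cfg: EvalConfig) -> EvalReport:
    """Repeated subject-disjoint n-fold CV (n_reps × n_folds fold evaluations)."""
    t0 = time.perf_counter()
    subject_ids = table.meta["subject_id"].to_numpy()
    global_sel = (fit_selection(table, cfg.selection)
                  if cfg.paper_mode and cfg.selection.mode != "none" else None)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 77)))
    folds = []
    for rep in range(cfg.n_reps):
        groups = subject_folds(subject_ids, cfg.n_folds, rng)
        val_sets = []
        for i, group in enumerate(groups):
            va = np.flatnonzero(np.isin(subject_ids, group))
            tr = np.flatnonzero(~np.isin(subject_ids, group))
            val_sets.append(va)
            train_subj = set(subject_ids[tr])
            if train_subj & set(group):
                raise AssertionError("subject appears in both train and val")
            m = _fit_eval_fold(table.take(tr), table.take(va), cfg, global_sel,
                               fold_seed=cfg.seed * 1000 + rep * 10 + i)
            folds.append(FoldResult(rep=rep, fold=i, metrics=m, n_val=len(va),
                                    val_subjects=tuple(sorted(group))))
        _check_partition(table.n_samples, val_sets)
    return EvalReport(scheme="cross_subject", folds=folds, seed=cfg.seed,
                      wall_clock_s=time.perf_counter() - t0,
                      selection_mode=cfg.selection.mode,
                      paper_mode=cfg.paper_mode)


ABLATION_CONDITIONS = {
    "FT": "none",  # no screening, no channel selection
    "AFT": "features",  # ANOVA screening only
    "ASFT": "features+channels",  # screening + channel selection
}


def ablation_run(table: FeatureTable, cfg: EvalConfig,
                 scheme: str = "cross_clip") -> dict[str, EvalReport]:
    """Run the chosen CV scheme under the three selection conditions."""
    runner = {"cross_clip": cross_clip_cv,
              "cross_subject": cross_subject_cv}[scheme]
    out: dict[str, EvalReport] = {}
    for label, mode in ABLATION_CONDITIONS.items():
        cond = replace(cfg, selection=replace(cfg.selection, mode=mode))
        out[label] = runner(table, cond)
        logger.info("%s: mean accuracy %.4f", label, out[label].mean_accuracy)
    return out
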