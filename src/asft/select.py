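"""Pivotal feature screening (one-way ANOVA) and channel selection (SVM + AUC).

Screening: a one-way ANOVA (alert vs fatigue) is run per (feature, band,
channel) column; a combination is significant at p < α (0.01 by default) and a
feature is retained when it is significant in at least ``min_combos`` of the
band × channel combinations (40 of 64 at full scale).

Channel selection: for every (channel, band) pair a soft-margin linear SVM is
trained on the retained features of that channel and band under stratified
k-fold cross-validation; validation decision values are scored with the
rank-based (Mann–Whitney) AUC, with the alert state as the positive class.
Channels are ranked by their cross-band mean AUC and the top k are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import BANDS, FEATURES, FeatureKey, FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """Per-column F/p values, per-feature significant-combo counts, retained set."""

    keys: tuple[FeatureKey, ...]
    F: np.ndarray
    p: np.ndarray
    alpha: float
    min_combos: int
    combo_counts: dict[str, int]
    n_combos: int
    retained_features: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "min_combos": self.min_combos,
            "n_combos": self.n_combos,
            "combo_counts": dict(self.combo_counts),
            "retained_features": list(self.retained_features),
            "p_values": {k.encode(): float(p) for k, p in zip(self.keys, self.p)},
        }


@dataclass
class ChannelAucResult:
    """Per-(channel, band) CV AUC, per-channel aggregate, ranking, retained set."""

    auc_mean: dict[tuple[str, str], float]  # (channel, band) → mean over folds
    auc_std: dict[tuple[str, str], float]
    channel_mean: dict[str, float]
    ranked_channels: tuple[str, ...]
    retained_channels: tuple[str, ...]
    k: int
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "auc": {f"{c}/{b}": {"mean": self.auc_mean[(c, b)],
                                 "std": self.auc_std[(c, b)]}
                    for (c, b) in self.auc_mean},
            "channel_mean_auc": dict(self.channel_mean),
            "ranked_channels": list(self.ranked_channels),
            "retained_channels": list(self.retained_channels),
        }


def anova_screen(table: FeatureTable, alpha: float = 0.01,
                 min_combos: int = 40) -> AnovaResult:
    """One-way ANOVA per column between the alert and fatigue groups.

    Zero-variance columns get p = 1 (logged) rather than raising. With two
    groups the ANOVA F statistic equals the squared pooled two-sample t.
    """
    y = table.y
    a, b = table.X[y > 0], table.X[y < 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both states need at least two samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(a, b, axis=0)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(F)
    if degenerate.any():
        logger.warning("%d zero-variance/degenerate columns: p set to 1",
                       int(degenerate.sum()))
        F = np.where(degenerate, 0.0, F)
        p = np.where(degenerate, 1.0, p)
    sig = p < alpha
    features = tuple(dict.fromkeys(k.feature for k in table.keys))
    combos_per_feature = {
        f: len({(k.band, k.channel) for k in table.keys if k.feature == f})
        for f in features}
    counts = {f: int(sum(s for s, k in zip(sig, table.keys) if k.feature == f))
              for f in features}
    retained = tuple(f for f in features if counts[f] >= min_combos)
    return AnovaResult(keys=table.keys, F=F, p=p, alpha=alpha,
                       min_combos=min_combos, combo_counts=counts,
                       n_combos=max(combos_per_feature.values()),
                       retained_features=retained)


def svm_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC of decision values against ±1 labels.

    Scores are ranked ascending with midranks for ties;
    AUC = (Σ ranks of positives − T(T+1)/2) / (T·F), which equals
    P(score⁺ > score⁻) + ½ P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    T, Fn = int(pos.sum()), int((~pos).sum())
    if T == 0 or Fn == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(scores)  # average (mid) ranks
    return float((ranks[pos].sum() - T * (T + 1) / 2.0) / (T * Fn))


def _column_keys(table: FeatureTable, channel: str, bands: Sequence[str],
                 features: Sequence[str]) -> list[FeatureKey]:
    idx = table.key_index()
    keys = [FeatureKey(b, f, channel) for b in bands for f in features]
    missing = [k for k in keys if k not in idx]
    if missing:
        raise KeyError(f"columns missing from table: {missing[:3]}...")
    return keys


def channel_band_auc(table: FeatureTable, channel: str, band: str | None,
                     retained_features: Sequence[str], n_folds: int = 10,
                     C: float = 1.0, seed: int = 0) -> tuple[float, float]:
    """Mean ± std CV AUC of a linear SVM on one channel's retained features.

    ``band=None`` trains on the retained features of all four bands at once
    (the cross-band variant); otherwise only that band's columns are used.
    Features are z-scored on each training split.
    """
    if not retained_features:
        raise ValueError("retained_features must be non-empty")
    bands = list(BANDS) if band is None else [band]
    sub = table.select_keys(_column_keys(table, channel, bands,
                                         retained_features))
    X, y = sub.X, sub.y
    counts = np.bincount((y > 0).astype(int))
    if counts.min() < n_folds:
        raise ValueError(f"need at least {n_folds} samples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(X[tr]), y[tr])
        # decision_function is positive toward class +1 (alert)
        aucs.append(svm_auc(clf.decision_function(scaler.transform(X[va])),
                            y[va]))
    return float(np.mean(aucs)), float(np.std(aucs))


def select_channels(table: FeatureTable, retained_features: Sequence[str],
                    k: int = 8, n_folds: int = 10, C: float = 1.0,
                    seed: int = 0) -> ChannelAucResult:
    """Rank channels by cross-band mean CV AUC and retain the top k.

    Ties are broken by channel-name lexical order (logged when they occur).
    """
    channels = tuple(dict.fromkeys(kk.channel for kk in table.keys))
    if k > len(channels):
        raise ValueError(f"k={k} exceeds the {len(channels)} channels present")
    bands = tuple(dict.fromkeys(kk.band for kk in table.keys))
    auc_mean: dict[tuple[str, str], float] = {}
    auc_std: dict[tuple[str, str], float] = {}
    for channel in channels:
        for band in bands:
            m, s = channel_band_auc(table, channel, band, retained_features,
                                    n_folds=n_folds, C=C, seed=seed)
            auc_mean[(channel, band)] = m
            auc_std[(channel, band)] = s
    channel_mean = {c: float(np.mean([auc_mean[(c, b)] for b in bands]))
                    for c in channels}
    ranked = tuple(sorted(channels, key=lambda c: (-channel_mean[c], c)))
    vals = sorted(channel_mean.values(), reverse=True)
    if len(vals) > k and vals[k - 1] == vals[k]:
        logger.warning("AUC tie at the retention boundary; broken lexically")
    return ChannelAucResult(auc_mean=auc_mean, auc_std=auc_std,
                            channel_mean=channel_mean, ranked_channels=ranked,
                            retained_channels=ranked[:k], k=k,
                            n_folds=n_folds, seed=seed)


def apply_selection(table: FeatureTable, retained_features: Sequence[str],
                    retained_channels: Sequence[str]) -> FeatureTable:
    """Column-subset the table to the retained features × channels (all bands)."""
    if not retained_features or not retained_channels:
        raise ValueError("retained sets must be non-empty")
    return table.subset(features=retained_features, channels=retained_channels)


@dataclass
class SelectionConfig:
    """Parameters of the screening + channel-selection stage."""

    mode: str = "features+channels"  # "none" | "features" | "features+channels"
    alpha: float = 0.01
    min_combos: int = 40
    k: int = 8
    svm_folds: int = 10
    svm_C: float = 1.0
    per_band: bool = True  # False → cross-band 24-feature SVM variant
    seed: int = 0


@dataclass
class Selection:
    """A fitted selection: retained sets plus the underlying reports."""

    retained_features: tuple[str, ...]
    retained_channels: tuple[str, ...] | None
    anova: AnovaResult | None = None
    channel_auc: ChannelAucResult | None = None

    def apply(self, table: FeatureTable) -> FeatureTable:
        if self.retained_channels is None:
            return table.subset(features=self.retained_features)
        return apply_selection(table, self.retained_features,
                               self.retained_channels)

    def to_dict(self) -> dict:
        return {
            "retained_features": list(self.retained_features),
            "retained_channels": (None if self.retained_channels is None
                                  else list(self.retained_channels)),
            "anova": self.anova.to_dict() if self.anova else None,
            "channel_auc": (self.channel_auc.to_dict()
                            if self.channel_auc else None),
        }


def fit_selection(table: FeatureTable, cfg: SelectionConfig) -> Selection:
    """Run the configured screening/selection stages on (training) data."""
    if cfg.mode == "none":
        feats = tuple(dict.fromkeys(k.feature for k in table.keys))
        return Selection(retained_features=feats, retained_channels=None)
    anova = anova_screen(table, alpha=cfg.alpha, min_combos=cfg.min_combos)
    if not anova.retained_features:
        raise ValueError(
            "ANOVA screening retained no features; lower min_combos or check "
            "that the two states actually differ")
    if cfg.mode == "features":
        return Selection(retained_features=anova.retained_features,
                         retained_channels=None, anova=anova)
    if cfg.mode != "features+channels":
        raise ValueError(f"unknown selection mode {cfg.mode!r}")
    chan = select_channels(table, anova.retained_features, k=cfg.k,
                           n_folds=cfg.svm_folds, C=cfg.svm_C, seed=cfg.seed)
    return Selection(retained_features=anova.retained_features,
                     retained_channels=chan.retained_channels,
                     anova=anova, channel_auc=chan)
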