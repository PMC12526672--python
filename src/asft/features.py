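"""Per-segment time- and frequency-domain features and feature-table assembly.

Each 2 s band-limited segment contributes eight features:

* time domain — mean (MEA), energy (ENE, Σx²), population variance (VAR),
  root mean square (RMS);
* frequency domain — band power-spectral density (PSD, mean in-band bin
  power), centroid frequency (CF), frequency variance (FV, second central
  spectral moment) and mean square frequency (MSF, second raw moment), all
  power-weighted over the segment's own DFT bins restricted to the band.

The spectral moments satisfy MSF = FV + CF² identically; amplitude scaling
leaves CF/FV/MSF unchanged and scales MEA/RMS linearly, ENE/VAR/PSD
quadratically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (BAND_EDGES, BANDS, FEATURES, FeatureKey, FeatureTable,
                 Recording, all_feature_keys)
from .preprocess import PreprocessConfig, Segment, band_mask, band_series, \
    segment_matrix

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One-sided power spectrum: |S(k)|² at bin frequencies k·fs/N."""

    freqs: np.ndarray
    power: np.ndarray  # (..., n_bins), non-negative

    def band_bins(self, band: str | tuple[float, float]) -> np.ndarray:
        return band_mask(self.freqs, band)


def time_features(samples: np.ndarray) -> dict[str, np.ndarray]:
    """MEA, ENE, VAR, RMS along the last axis (vectorised over leading axes)."""
    x = np.asarray(samples, dtype=np.float64)
    if x.shape[-1] < 1:
        raise ValueError("empty segment")
    mea = x.mean(axis=-1)
    ene = (x * x).sum(axis=-1)
    var = x.var(axis=-1)  # population form, 1/N
    rms = np.sqrt(ene / x.shape[-1])
    return {"MEA": mea, "ENE": ene, "VAR": var, "RMS": rms}


def spectrum(samples: np.ndarray, fs: float) -> Spectrum:
    """One-sided power spectrum of the segment (rectangular window)."""
    x = np.asarray(samples, dtype=np.float64)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("segment too short for a spectrum")
    s = np.fft.rfft(x, axis=-1)
    return Spectrum(freqs=np.fft.rfftfreq(n, d=1.0 / fs),
                    power=np.abs(s) ** 2)


def freq_features(spec: Spectrum, band: str | tuple[float, float],
                  ) -> dict[str, np.ndarray]:
    """PSD, CF, FV, MSF of the band's bins (vectorised over leading axes).

    With zero total band power the weighted moments are undefined: CF/FV/MSF
    come back NaN (logged) while PSD is 0.
    """
    mask = spec.band_bins(band)
    if not mask.any():
        raise ValueError(f"band {band!r} contains no spectral bins")
    f = spec.freqs[mask]
    w = spec.power[..., mask]
    total = w.sum(axis=-1)
    psd = total / mask.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(total > 0, total, np.nan)
        cf = (w * f).sum(axis=-1) / denom
        msf = (w * f ** 2).sum(axis=-1) / denom
        fv = (w * (f - np.expand_dims(cf, -1)) ** 2).sum(axis=-1) / denom
    if np.isnan(np.atleast_1d(cf)).any():
        logger.warning("zero band power in %s: CF/FV/MSF undefined (NaN)",
                       band)
    return {"PSD": psd, "CF": cf, "FV": fv, "MSF": msf}


def segment_features(samples: np.ndarray, fs: float,
                     band: str | tuple[float, float]) -> dict[str, np.ndarray]:
    """All eight features of one or more segments (last axis = time)."""
    out = time_features(samples)
    out.update(freq_features(spectrum(samples, fs), band))
    return out


def _meta_frame(meta: Mapping[str, str], n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [str(meta["subject_id"])] * n,
        "session": [meta["session"]] * n,
        "state": [meta["state"]] * n,
        "segment_index": np.arange(n),
    })


def extract_features(segments: Sequence[Segment], fs: float,
                     meta: Mapping[str, str] | None = None) -> FeatureTable:
    """Assemble a feature table from one recording's segments.

    One row per segment_index, one column per (band, feature, channel) in
    canonical order (bands outer, features inner, channels innermost). All
    (channel, band) groups must share an aligned segment grid.
    """
    if not segments:
        raise ValueError("no segments")
    groups: dict[tuple[str, str], list[Segment]] = {}
    for s in segments:
        groups.setdefault((s.band, s.channel), []).append(s)
    counts = {len(v) for v in groups.values()}
    if len(counts) != 1:
        raise ValueError("mismatched segment grids across channels/bands")
    n_rows = counts.pop()
    bands = tuple(dict.fromkeys(s.band for s in segments))
    channels = tuple(dict.fromkeys(s.channel for s in segments))
    keys = all_feature_keys(channels=channels, bands=bands)
    X = np.empty((n_rows, len(keys)))
    col = {k: i for i, k in enumerate(keys)}
    for (band, channel), segs in groups.items():
        segs = sorted(segs, key=lambda s: s.segment_index)
        if [s.segment_index for s in segs] != list(range(n_rows)):
            raise ValueError("segment indices are not an aligned 0..n-1 grid")
        feats = segment_features(np.stack([s.samples for s in segs]), fs, band)
        for name in FEATURES:
            X[:, col[FeatureKey(band, name, channel)]] = feats[name]
    meta = meta or {"subject_id": "?", "session": "pre", "state": "alert"}
    return FeatureTable(X, keys, _meta_frame(meta, n_rows))


def features_for_recording(rec: Recording,
                           cfg: PreprocessConfig | None = None) -> FeatureTable:
    """Preprocess one recording and extract its full feature table.

    Vectorised fast path: band decomposition once per recording, then all
    windows of a channel-band series are featurised as a single matrix.
    """
    cfg = cfg or PreprocessConfig()
    series = band_series(rec, cfg)
    keys = all_feature_keys(channels=rec.channels,
                            bands=tuple(cfg.band_edges))
    col = {k: i for i, k in enumerate(keys)}
    X: np.ndarray | None = None
    for band, mat in series.items():
        for ci, channel in enumerate(rec.channels):
            wins = segment_matrix(mat[ci], rec.fs, cfg.win_seconds, cfg.overlap)
            feats = segment_features(wins, rec.fs, band)
            if X is None:
                X = np.empty((wins.shape[0], len(keys)))
            for name in FEATURES:
                X[:, col[FeatureKey(band, name, channel)]] = feats[name]
    assert X is not None
    return FeatureTable(X, keys, _meta_frame(
        {"subject_id": rec.subject_id, "session": rec.session,
         "state": rec.state}, X.shape[0]))


def extract_study_features(recordings: Sequence[Recording],
                           cfg: PreprocessConfig | None = None) -> FeatureTable:
    """Concatenate per-recording feature tables for a whole study.

    32 subjects × 2 sessions × 10 min at 500 Hz → 38,336 rows × 512 columns.
    """
    return FeatureTable.concat([features_for_recording(r, cfg)
                                for r in recordings])
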