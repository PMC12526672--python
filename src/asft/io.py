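"""Domain types and readers/writers for EEG recordings, feature tables and reports.

The pipeline operates on three containers:

* :class:`Recording` — one subject/session multichannel EEG trace.
* :class:`FeatureTable` — samples × (band, feature, channel) feature matrix with
  per-row subject/session/state metadata.
* plain-dict reports, serialised as JSON by the callers.

CSV is the canonical on-disk format (full double precision, header mandatory);
EDF is supported read-only through :mod:`mne`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical band order and edges in Hz; intervals are half-open [low, high)
#: except beta, which is closed at 30 Hz so the four bands tile [0.5, 30].
BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: the eight per-segment features: four time-domain, four frequency-domain.
TIME_FEATURES: tuple[str, ...] = ("MEA", "ENE", "VAR", "RMS")
FREQ_FEATURES: tuple[str, ...] = ("PSD", "CF", "FV", "MSF")
FEATURES: tuple[str, ...] = TIME_FEATURES + FREQ_FEATURES

#: 16-channel 10–20 montage used by default.
STANDARD_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "C3", "C4",
    "P3", "P4", "T3", "T4", "T5", "T6", "O1", "O2",
)

_REGION_BY_PREFIX = {
    "FP": "Frontopolar",
    "F": "Frontal",
    "C": "Central",
    "P": "Parietal",
    "T": "Temporal",
    "O": "Occipital",
}

SESSIONS = ("pre", "post")
STATES = ("alert", "fatigue")
#: numeric labels used by the SVM stage: alert = +1 (positive class), fatigue = −1.
STATE_TO_Y = {"alert": 1, "fatigue": -1}


def normalize_channel(name: str) -> str:
    """Normalise an electrode label across EDF dialects (``Fp1``/``EEG FP1`` → ``FP1``)."""
    name = name.strip()
    if name.upper().startswith("EEG "):
        name = name[4:]
    return name.strip().upper()


def channel_region(name: str) -> str | None:
    """Return the cortical region of a 10–20 label, or None if unrecognised."""
    name = normalize_channel(name)
    if name[:2] == "FP":
        return _REGION_BY_PREFIX["FP"]
    if name[:1] in _REGION_BY_PREFIX and name[1:].isdigit():
        return _REGION_BY_PREFIX[name[:1]]
    return None


@dataclass(frozen=True)
class ChannelLayout:
    """An ordered electrode montage with a channel → region map."""

    names: tuple[str, ...] = STANDARD_CHANNELS

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names in layout")

    def __contains__(self, name: str) -> bool:
        return normalize_channel(name) in self.names

    def region_of(self, name: str) -> str | None:
        return channel_region(name)


@dataclass
class Recording:
    """One subject/session multichannel EEG trace.

    data is channel-major, shape ``(n_channels, n_samples)``, in microvolts
    (never rescaled by the pipeline).
    """

    subject_id: str
    session: str  # "pre" | "post"
    state: str  # "alert" | "fatigue"
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.channels = tuple(normalize_channel(c) for c in self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names")
        if len(self.channels) < 1:
            raise ValueError("need at least one channel")
        unknown = [c for c in self.channels if c not in STANDARD_CHANNELS]
        if unknown:
            logger.warning(
                "recording %s/%s: channels not in the standard 16-channel layout: %s",
                self.subject_id, self.session, unknown,
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def y(self) -> int:
        """±1 state label (alert = +1, fatigue = −1)."""
        return STATE_TO_Y[self.state]

    def channel_data(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(normalize_channel(name))]


class FeatureKey(NamedTuple):
    """Identifies one feature column: (band, feature, channel)."""

    band: str
    feature: str
    channel: str

    def encode(self) -> str:
        return f"{self.band}__{self.feature}__{self.channel}"

    @classmethod
    def decode(cls, text: str) -> "FeatureKey":
        parts = text.split("__")
        if len(parts) != 3:
            raise ValueError(f"not a feature-column key: {text!r}")
        band, feature, channel = parts
        if band not in BANDS:
            raise ValueError(f"unknown band in key {text!r}")
        if feature not in FEATURES:
            raise ValueError(f"unknown feature in key {text!r}")
        return cls(band, feature, channel)


META_COLUMNS = ("subject_id", "session", "state", "segment_index")


@dataclass
class FeatureTable:
    """Samples × feature-columns matrix with per-row metadata.

    With the full 16-channel layout, 8 features and 4 bands the table has
    4 × 8 × 16 = 512 columns; after retaining 6 features and 8 channels,
    4 × 6 × 8 = 192.
    """

    X: np.ndarray
    keys: tuple[FeatureKey, ...]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.keys = tuple(FeatureKey(*k) for k in self.keys)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != len(self.keys):
            raise ValueError("number of keys must match number of columns")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate feature-column keys")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta must have one row per sample")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns {missing}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        """±1 labels per row (alert = +1, fatigue = −1)."""
        return self.meta["state"].map(STATE_TO_Y).to_numpy()

    def key_index(self) -> dict[FeatureKey, int]:
        return {k: i for i, k in enumerate(self.keys)}

    def select_keys(self, keys: Sequence[FeatureKey]) -> "FeatureTable":
        idx = self.key_index()
        cols = [idx[FeatureKey(*k)] for k in keys]
        return FeatureTable(self.X[:, cols], tuple(self.keys[c] for c in cols),
                            self.meta.copy())

    def subset(self, bands: Iterable[str] | None = None,
               features: Iterable[str] | None = None,
               channels: Iterable[str] | None = None) -> "FeatureTable":
        """Column subset; canonical ordering of the surviving keys is preserved."""
        bands = set(bands) if bands is not None else None
        features = set(features) if features is not None else None
        channels = set(channels) if channels is not None else None
        keep = [
            k for k in self.keys
            if (bands is None or k.band in bands)
            and (features is None or k.feature in features)
            and (channels is None or k.channel in channels)
        ]
        if not keep:
            raise ValueError("selection removed every column")
        return self.select_keys(keep)

    def take(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[rows], self.keys,
                            self.meta.iloc[rows].reset_index(drop=True))

    @classmethod
    def concat(cls, tables: Sequence["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        keys = tables[0].keys
        for t in tables[1:]:
            if t.keys != keys:
                raise ValueError("tables have different column keys")
        return cls(np.vstack([t.X for t in tables]), keys,
                   pd.concat([t.meta for t in tables], ignore_index=True))

    def to_dataframe(self) -> pd.DataFrame:
        values = pd.DataFrame(self.X, columns=[k.encode() for k in self.keys])
        return pd.concat([self.meta.loc[:, list(META_COLUMNS)], values],
                         axis=1)


def read_recording(path: str | Path, format: str | None = None, *,
                   subject_id: str, session: str, state: str,
                   fs: float | None = None) -> Recording:
    """Read a multichannel EEG recording from CSV or EDF.

    CSV files need a header row of channel names (one column per channel) and
    an explicit ``fs``; EDF files carry their own sampling rate and labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        if fs is None:
            raise ValueError("fs is required when reading CSV recordings")
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")
        if len(set(header)) != len(header):
            raise ValueError("duplicate channel names in CSV header")
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] < 1:
            raise ValueError("recording has no channels")
        bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
        if len(bad):
            raise ValueError(f"non-numeric cells in columns {list(bad)}")
        channels = tuple(str(c) for c in df.columns)
        data = df.to_numpy(dtype=np.float64).T
    elif format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        channels = tuple(raw.ch_names)
        fs = float(raw.info["sfreq"])
        # mne rescales EDF voltages to volts; bring them back to microvolts.
        data = raw.get_data() * 1e6
    else:
        raise ValueError(f"unknown format {format!r}")
    return Recording(subject_id=subject_id, session=session, state=state,
                     fs=float(fs), channels=channels, data=data)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV (header of channel names, one row per sample)."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channels))
    df.to_csv(path, index=False)
    return path


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table as CSV: 4 metadata columns then one column per key."""
    if table.n_samples == 0 or table.n_columns == 0:
        raise ValueError("refusing to write an empty feature table")
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature-table file is missing metadata columns {missing}")
    key_cols = [c for c in df.columns if c not in META_COLUMNS]
    keys = tuple(FeatureKey.decode(c) for c in key_cols)
    if len(set(keys)) != len(keys):
        raise ValueError("key collision while parsing feature-table columns")
    meta = df.loc[:, list(META_COLUMNS)].copy()
    meta["subject_id"] = meta["subject_id"].astype(str)
    return FeatureTable(df.loc[:, key_cols].to_numpy(dtype=np.float64), keys, meta)


def all_feature_keys(channels: Sequence[str] = STANDARD_CHANNELS,
                     bands: Sequence[str] = BANDS,
                     features: Sequence[str] = FEATURES) -> tuple[FeatureKey, ...]:
    """Canonical column ordering: bands outer, features inner, channels innermost."""
    return tuple(FeatureKey(b, f, c) for b in bands for f in features for c in channels)
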