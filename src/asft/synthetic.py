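"""Seeded generator of synthetic multichannel EEG studies.

Each channel is a sum over the four canonical bands of band-limited Gaussian
noise (white noise FFT-masked to the band, normalised to unit RMS), scaled by

    band amplitude × subject random effect × state factor,

plus broadband measurement noise. Fatigue is modelled as band-amplitude
modulation only: θ amplitude up (×1.4 by default), α and β down (×0.7), δ
unchanged — the classical band-power signature of drowsiness — carried in
full by a pivotal channel subset (occipital strongest, then central/temporal,
then frontopolar) and at 15 % strength elsewhere. Subject-level amplitude
random effects are shared between a subject's two sessions, which is what
creates the cross-clip vs cross-subject generalisation gap.

Everything is deterministic given (seed, subject index, state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BANDS, Recording, STANDARD_CHANNELS
from .preprocess import band_mask


def _default_channel_weights() -> dict[str, float]:
    # relative strength of the fatigue effect on the pivotal channels
    return {"O1": 1.0, "O2": 1.0, "C3": 0.85, "C4": 0.85,
            "T3": 0.85, "T4": 0.85, "FP1": 0.7, "FP2": 0.7}


@dataclass
class SimConfig:
    """Study-level generator settings (defaults emulate the target study)."""

    n_subjects: int = 32
    fs: float = 500.0
    duration_s: float = 600.0
    channels: tuple[str, ...] = STANDARD_CHANNELS
    band_base_amp: dict[str, float] = field(default_factory=lambda: {
        "delta": 20.0, "theta": 10.0, "alpha": 12.0, "beta": 6.0})  # µV RMS
    fatigue_effect: dict[str, float] = field(default_factory=lambda: {
        "delta": 1.0, "theta": 1.4, "alpha": 0.7, "beta": 0.7})
    effect_channels: tuple[str, ...] = (
        "O1", "O2", "T3", "T4", "C3", "C4", "FP1", "FP2")
    channel_effect_weights: dict[str, float] = field(
        default_factory=_default_channel_weights)
    off_effect_attenuation: float = 0.15
    subject_sd: float = 0.2  # lognormal sd of per-subject band amplitudes
    noise_amp: float = 2.0  # µV RMS of broadband measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.band_base_amp.values()):
            raise ValueError("band amplitudes must be positive")
        if any(f <= 0 for f in self.fatigue_effect.values()):
            raise ValueError("fatigue effect factors must be positive")
        unknown = set(self.effect_channels) - set(self.channels)
        if unknown:
            raise ValueError(f"effect channels not in layout: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def effect_weight(self, channel: str) -> float:
        if channel in self.effect_channels:
            return self.channel_effect_weights.get(channel, 1.0)
        return self.off_effect_attenuation

    def state_factor(self, band: str, channel: str, state: str) -> float:
        if state == "alert":
            return 1.0
        return 1.0 + (self.fatigue_effect[band] - 1.0) * self.effect_weight(channel)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        edges: tuple[float, float] | str) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to one band by FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    mask = band_mask(np.fft.rfftfreq(n, d=1.0 / fs),
                     edges if isinstance(edges, str) else tuple(edges))
    x = np.fft.irfft(spec * mask, n=n)
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def subject_effects(cfg: SimConfig, subject_index: int) -> dict[str, float]:
    """Per-subject lognormal band-amplitude random effects (state-independent)."""
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, 1, subject_index)))
    return {band: float(np.exp(rng.normal(0.0, cfg.subject_sd)))
            for band in BANDS}


def simulate_recording(subject_index: int, state: str, cfg: SimConfig,
                       ) -> Recording:
    """One synthetic recording, fully determined by (cfg.seed, subject, state)."""
    if state not in ("alert", "fatigue"):
        raise ValueError(f"unknown state {state!r}")
    n = cfg.n_samples
    subj = subject_effects(cfg, subject_index)
    rng = np.random.default_rng(np.random.SeedSequence(
        (cfg.seed, 2, subject_index, 0 if state == "alert" else 1)))
    data = np.empty((len(cfg.channels), n))
    for ci, channel in enumerate(cfg.channels):
        x = cfg.noise_amp * rng.standard_normal(n)
        for band in BANDS:
            amp = (cfg.band_base_amp[band] * subj[band]
                   * cfg.state_factor(band, channel, state))
            x = x + amp * _band_limited_noise(rng, n, cfg.fs, band)
        data[ci] = x
    return Recording(subject_id=f"S{subject_index:02d}",
                     session="pre" if state == "alert" else "post",
                     state=state, fs=cfg.fs, channels=cfg.channels, data=data)


def simulate_study(cfg: SimConfig) -> list[Recording]:
    """One alert (pre) and one fatigue (post) recording per subject."""
    recs: list[Recording] = []
    for i in range(cfg.n_subjects):
        recs.append(simulate_recording(i, "alert", cfg))
        recs.append(simulate_recording(i, "fatigue", cfg))
    return recs


def null_config(cfg: SimConfig | None = None) -> SimConfig:
    """A copy with all fatigue effects at 1.0 (alert/fatigue indistinguishable)."""
    cfg = cfg or SimConfig()
    return replace(cfg, fatigue_effect={b: 1.0 for b in BANDS})


def scaled_effect_config(cfg: SimConfig, scale: float) -> SimConfig:
    """Scale every band's deviation from 1.0 by ``scale`` (0 → null, 1 → as-is)."""
    eff = {b: 1.0 + (f - 1.0) * scale for b, f in cfg.fatigue_effect.items()}
    return replace(cfg, fatigue_effect=eff)
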