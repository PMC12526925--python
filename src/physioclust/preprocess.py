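"""Signal conditioning: ACC low-pass, ECG band-pass + decimation +
min–max normalization, and fixed-window segment extraction.

The chain mirrors a typical wearable pipeline: movement content below
6 Hz is kept on the accelerometer; the ECG is band-limited to 5–15 Hz
(QRS energy, baseline drift removed), decimated to 500 Hz and min–max
normalized per channel to suppress electrode/skin amplitude variability;
finally a representative 7 s window is cut from every channel at the
same absolute time offset.

All filters are applied zero-phase (forward–backward Butterworth) so the
two modalities stay temporally comparable; a causal mode is available
for the ACC low-pass via ``acc_zero_phase=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import ACC_KINDS, ECG_KINDS, SignalChannel, Trial


@dataclass(frozen=True)
class PreprocessConfig:
    acc_cutoff_hz: float = 6.0
    acc_order: int = 4
    ecg_band_hz: tuple[float, float] = (5.0, 15.0)
    ecg_order: int = 4
    ecg_target_rate: float = 500.0
    segment_s: float = 7.0
    segment_offset_s: float = 1.0
    acc_zero_phase: bool = True

    def __post_init__(self) -> None:
        low, high = self.ecg_band_hz
        if not 0 < low < high:
            raise ValueError("ecg_band_hz must satisfy 0 < low < high")
        if self.segment_s <= 0 or self.segment_offset_s < 0:
            raise ValueError("segment window must be positive, offset non-negative")


def lowpass_acc(channel: SignalChannel, config: PreprocessConfig | None = None) -> SignalChannel:
    """Fourth-order Butterworth low-pass (6 Hz default) on an ACC axis."""
    config = config or PreprocessConfig()
    if channel.kind not in ACC_KINDS:
        raise ValueError(f"lowpass_acc expects an ACC channel, got {channel.kind}")
    sos = sps.butter(config.acc_order, config.acc_cutoff_hz, btype="low", fs=channel.rate, output="sos")
    if config.acc_zero_phase:
        filtered = sps.sosfiltfilt(sos, channel.samples)
    else:
        filtered = sps.sosfilt(sos, channel.samples)
    return replace(channel, samples=filtered)


def bandpass_ecg(channel: SignalChannel, config: PreprocessConfig | None = None) -> SignalChannel:
    """Fourth-order zero-phase Butterworth band-pass (5–15 Hz default)."""
    config = config or PreprocessConfig()
    if channel.kind not in ECG_KINDS:
        raise ValueError(f"bandpass_ecg expects an ECG channel, got {channel.kind}")
    low, high = config.ecg_band_hz
    if high >= channel.rate / 2:
        raise ValueError("band upper edge must be below Nyquist")
    sos = sps.butter(config.ecg_order, (low, high), btype="band", fs=channel.rate, output="sos")
    return replace(channel, samples=sps.sosfiltfilt(sos, channel.samples))


def decimate_ecg(channel: SignalChannel, config: PreprocessConfig | None = None) -> SignalChannel:
    """Anti-aliased decimation to ``ecg_target_rate``.

    Zero-phase 8th-order Butterworth low-pass at 0.8 × the new Nyquist,
    then every k-th sample is kept (k = integer rate ratio).
    """
    config = config or PreprocessConfig()
    if channel.kind not in ECG_KINDS:
        raise ValueError(f"decimate_ecg expects an ECG channel, got {channel.kind}")
    ratio = channel.rate / config.ecg_target_rate
    k = round(ratio)
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"source rate {channel.rate} is not an integer multiple of target {config.ecg_target_rate}"
        )
    if k == 1:
        return channel
    cutoff = 0.8 * (config.ecg_target_rate / 2.0)
    sos = sps.butter(8, cutoff, btype="low", fs=channel.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, channel.samples)
    return replace(channel, samples=filtered[::k], rate=config.ecg_target_rate)


def minmax_normalize(channel: SignalChannel) -> SignalChannel:
    """Affine map of the channel onto [0, 1] (per channel, per trial).

    A constant channel maps to all zeros with a warning rather than
    raising, so degenerate inputs do not abort a batch run.
    """
    x = channel.samples
    if len(x) < 2:
        raise ValueError("minmax_normalize needs at least 2 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        warnings.warn(
            f"constant channel {channel.kind.value}: min-max normalization returns zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return replace(channel, samples=np.zeros_like(x), units="normalized")
    return replace(channel, samples=(x - lo) / (hi - lo), units="normalized")


def extract_segment(trial: Trial, config: PreprocessConfig | None = None) -> Trial:
    """Cut all five channels to the window [offset, offset + segment_s)."""
    config = config or PreprocessConfig()
    t0, dur = config.segment_offset_s, config.segment_s
    if trial.duration_s + 1e-9 < t0 + dur:
        raise ValueError(
            f"trial {trial.trial_id} ({trial.duration_s:.2f} s) too short for "
            f"offset {t0} s + segment {dur} s"
        )
    channels = {}
    for kind, ch in trial.channels.items():
        start = round(t0 * ch.rate)
        n = round(dur * ch.rate)
        channels[kind] = replace(ch, samples=ch.samples[start : start + n])
    return Trial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        activity=trial.activity,
        channels=channels,
    )


def preprocess_trial(trial: Trial, config: PreprocessConfig | None = None) -> Trial:
    """Full conditioning chain; segment extraction comes last."""
    config = config or PreprocessConfig()
    channels = {}
    for kind in ACC_KINDS:
        channels[kind] = lowpass_acc(trial.channels[kind], config)
    for kind in ECG_KINDS:
        ch = bandpass_ecg(trial.channels[kind], config)
        ch = decimate_ecg(ch, config)
        channels[kind] = minmax_normalize(ch)
    staged = Trial(
        trial_id=trial.trial_id,
        subject_id=trial.subject_id,
        activity=trial.activity,
        channels=channels,
    )
    return extract_segment(staged, config)


class TrialPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer applying the conditioning chain.

    ``transform`` maps a list of raw :class:`Trial` objects to their
    preprocessed counterparts; the transformer is stateless (``fit`` is
    a no-op kept for pipeline compatibility).
    """

    def __init__(
        self,
        acc_cutoff_hz: float = 6.0,
        acc_order: int = 4,
        ecg_band_hz: tuple[float, float] = (5.0, 15.0),
        ecg_order: int = 4,
        ecg_target_rate: float = 500.0,
        segment_s: float = 7.0,
        segment_offset_s: float = 1.0,
        acc_zero_phase: bool = True,
    ):
        self.acc_cutoff_hz = acc_cutoff_hz
        self.acc_order = acc_order
        self.ecg_band_hz = ecg_band_hz
        self.ecg_order = ecg_order
        self.ecg_target_rate = ecg_target_rate
        self.segment_s = segment_s
        self.segment_offset_s = segment_offset_s
        self.acc_zero_phase = acc_zero_phase

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            acc_cutoff_hz=self.acc_cutoff_hz,
            acc_order=self.acc_order,
            ecg_band_hz=tuple(self.ecg_band_hz),
            ecg_order=self.ecg_order,
            ecg_target_rate=self.ecg_target_rate,
            segment_s=self.segment_s,
            segment_offset_s=self.segment_offset_s,
            acc_zero_phase=self.acc_zero_phase,
        )

    def fit(self, X: list[Trial], y=None):
        return self

    def transform(self, X: list[Trial]) -> list[Trial]:
        cfg = self._config()
        return [preprocess_trial(tr, cfg) for tr in X]
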