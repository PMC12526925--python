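"""Synthetic cohorts of chest-worn accelerometer + two-lead ECG trials.

Emulates a wearable recording protocol: a chest module samples triaxial
acceleration (ACC, units of g, 100 Hz) and two bipolar ECG leads (1000 Hz)
while a subject performs one of six activities of daily living.  The
generator encodes the two axes of structure the downstream pipeline is
meant to recover:

* **subject identity** — a per-subject cardiac beat template (P/Q/R/S/T
  Gaussian bumps with subject-specific amplitudes and widths), resting
  heart rate, gait cadence and accelerometer gain;
* **activity** — a posture-dependent gravity component plus
  activity-specific oscillation amplitudes and frequencies on each ACC
  axis, and a heart-rate multiplier on the ECG.

Two ``separability`` knobs in ``[0, 1]`` scale how far subjects
(respectively activities) are spread around the population mean: 0 makes
all subjects (activities) statistically identical, 1 applies the full
documented spread.  Every generator is a pure function of its arguments
including the seed.

Chest-frame convention: y is longitudinal (gravity −1 g when upright),
x mediolateral, z anteroposterior; lying rotates gravity into z.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation


class ActivityLabel(str, Enum):
    """The six activities of daily living covered by the protocol."""

    WORKING = "working"
    UPSTAIRS = "upstairs"
    DOWNSTAIRS = "downstairs"
    WALKING = "walking"
    LYING = "lying"
    RESTING = "resting"


class ChannelKind(str, Enum):
    ACC_X = "ACC_X"
    ACC_Y = "ACC_Y"
    ACC_Z = "ACC_Z"
    ECG_1 = "ECG_1"
    ECG_2 = "ECG_2"


ACC_KINDS = (ChannelKind.ACC_X, ChannelKind.ACC_Y, ChannelKind.ACC_Z)
ECG_KINDS = (ChannelKind.ECG_1, ChannelKind.ECG_2)

#: activities with a periodic movement component
DYNAMIC_ACTIVITIES = frozenset(
    {ActivityLabel.WORKING, ActivityLabel.UPSTAIRS, ActivityLabel.DOWNSTAIRS, ActivityLabel.WALKING}
)
STATIC_ACTIVITIES = frozenset({ActivityLabel.LYING, ActivityLabel.RESTING})


@dataclass(frozen=True)
class SignalChannel:
    """One sampled channel of a trial."""

    kind: ChannelKind
    samples: np.ndarray
    rate: float
    units: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass(frozen=True)
class Trial:
    """One recording session: five synchronized channels plus labels."""

    trial_id: str
    subject_id: str
    activity: ActivityLabel
    channels: dict[ChannelKind, SignalChannel]

    def __post_init__(self) -> None:
        missing = [k for k in ChannelKind if k not in self.channels]
        if missing:
            raise ValueError(f"trial {self.trial_id} missing channels {missing}")
        acc_rates = {self.channels[k].rate for k in ACC_KINDS}
        ecg_rates = {self.channels[k].rate for k in ECG_KINDS}
        if len(acc_rates) != 1 or len(ecg_rates) != 1:
            raise ValueError("homologous channels must share one sampling rate")

    @property
    def acc_rate(self) -> float:
        return self.channels[ChannelKind.ACC_X].rate

    @property
    def ecg_rate(self) -> float:
        return self.channels[ChannelKind.ECG_1].rate

    @property
    def duration_s(self) -> float:
        return self.channels[ChannelKind.ACC_X].duration_s


@dataclass(frozen=True)
class SubjectParams:
    """Morphological and gait parameters of one simulated subject.

    ``qrs_amplitudes`` has shape (2 leads, 5 waves) ordered P, Q, R, S, T
    in arbitrary units; ``qrs_widths`` are the Gaussian sigmas of the five
    waves in seconds (shared across leads).
    """

    subject_id: str
    hr_rest: float
    qrs_amplitudes: np.ndarray
    qrs_widths: np.ndarray
    cadence_hz: float
    acc_amp_scale: float
    orientation_jitter_deg: float
    qrs_offsets: np.ndarray | None = None  # wave centers relative to R (s)

    def __post_init__(self) -> None:
        object.__setattr__(self, "qrs_amplitudes", np.asarray(self.qrs_amplitudes, float))
        object.__setattr__(self, "qrs_widths", np.asarray(self.qrs_widths, float))
        if self.qrs_offsets is None:
            object.__setattr__(self, "qrs_offsets", _QRS_OFFSETS.copy())
        else:
            object.__setattr__(self, "qrs_offsets", np.asarray(self.qrs_offsets, float))
        if not 40.0 <= self.hr_rest <= 180.0:
            raise ValueError(f"hr_rest {self.hr_rest} outside [40, 180]")
        if np.any(self.qrs_widths <= 0):
            raise ValueError("qrs_widths must be positive")
        if not 1.2 <= self.cadence_hz <= 2.6:
            raise ValueError(f"cadence_hz {self.cadence_hz} outside [1.2, 2.6]")
        if self.acc_amp_scale <= 0:
            raise ValueError("acc_amp_scale must be positive")


@dataclass(frozen=True)
class ActivityParams:
    """Per-activity movement model: posture gravity + per-axis oscillation."""

    gravity_vector: np.ndarray  # chest frame, units of g, |v| ~ 1
    osc_freq_hz: np.ndarray  # per-axis dominant frequency, 0 for static
    osc_amp_g: np.ndarray  # per-axis oscillation std target
    hr_multiplier: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gravity_vector", np.asarray(self.gravity_vector, float))
        object.__setattr__(self, "osc_freq_hz", np.asarray(self.osc_freq_hz, float))
        object.__setattr__(self, "osc_amp_g", np.asarray(self.osc_amp_g, float))
        if np.any(self.osc_amp_g < 0):
            raise ValueError("osc_amp_g must be non-negative")


@dataclass(frozen=True)
class Separability:
    activity: float = 1.0
    subject: float = 1.0

    def __post_init__(self) -> None:
        for name in ("activity", "subject"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"separability.{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 10
    activities: tuple[ActivityLabel, ...] = tuple(ActivityLabel)
    duration_s: float = 10.0
    acc_rate: float = 100.0
    ecg_rate: float = 1000.0
    noise_acc_g: float = 0.02
    noise_ecg: float = 0.02
    separability: Separability = field(default_factory=Separability)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s < 9.0:
            raise ValueError("duration_s must be >= 9 (7 s segment plus transient margin)")
        if self.acc_rate <= 0 or self.ecg_rate <= 0:
            raise ValueError("sampling rates must be positive")
        acts = tuple(ActivityLabel(a) for a in self.activities)
        object.__setattr__(self, "activities", acts)
        if isinstance(self.separability, dict):
            object.__setattr__(self, "separability", Separability(**self.separability))


# ---------------------------------------------------------------------------
# population-level calibration constants
# ---------------------------------------------------------------------------

#: population mean beat template: rows = leads, cols = P, Q, R, S, T
_POP_QRS_AMP = np.array(
    [
        [0.12, -0.18, 1.00, -0.25, 0.32],
        [0.08, -0.12, 0.70, -0.30, 0.45],
    ]
)
#: Gaussian sigma of each wave (s)
_POP_QRS_WIDTH = np.array([0.045, 0.012, 0.014, 0.013, 0.060])
#: wave centers relative to the R peak (s)
_QRS_OFFSETS = np.array([-0.16, -0.025, 0.0, 0.025, 0.22])

_POP_HR_REST = 70.0
_HR_SPREAD = 20.0  # bpm half-range at full subject separability (uniform)
#: per-wave coefficient of variation of the P/Q/R/S/T amplitudes at full
#: subject separability.  Identity information that survives per-lead
#: min–max normalization lives in the wave-to-R amplitude ratios; the
#: inter-individual variation of Q/S depth and P/T amplitude is large
#: (polarity variants included) while relative R variation is moderate.
QRS_AMP_CV = np.array([0.6, 0.8, 0.25, 0.8, 0.6])
_QRS_WIDTH_CV = 0.20
#: relative spread of the P/Q/S/T wave centers around their population
#: positions (the R peak stays the time origin)
_QRS_OFFSET_CV = 0.15
_POP_CADENCE = 1.9
_CADENCE_SPREAD = 0.35  # Hz std at full subject separability
_ACC_SCALE_SIGMA = 0.15  # log-scale std of the per-subject ACC gain
_ORIENTATION_DEG = 4.0  # std of sensor-tilt jitter at full separability

#: ratio between oscillation std and fundamental amplitude when a 30%
#: second harmonic is present: sqrt((1 + 0.3**2) / 2)
_HARMONIC_STD_RATIO = float(np.sqrt((1.0 + 0.09) / 2.0))
_RR_JITTER_FRAC = 0.03  # RR-interval jitter, fraction of mean RR


def _base_activity_params() -> dict[ActivityLabel, ActivityParams]:
    """Full-separability activity table.

    Gait tasks put their dominant oscillation on the longitudinal y axis
    (stairs strongest, ~0.2 g), floor cleaning concentrates movement on
    the mediolateral/anteroposterior axes, and the static postures carry
    no oscillation at all.  Stair tasks tilt the torso slightly forward
    (upstairs) or backward (downstairs).
    """

    def grav(x, y, z):
        v = np.array([x, y, z], float)
        return v / np.linalg.norm(v)

    return {
        ActivityLabel.RESTING: ActivityParams(
            gravity_vector=grav(0.0, -1.0, 0.0),
            osc_freq_hz=np.zeros(3),
            osc_amp_g=np.zeros(3),
            hr_multiplier=1.0,
        ),
        ActivityLabel.LYING: ActivityParams(
            gravity_vector=grav(0.0, -0.08, -1.0),
            osc_freq_hz=np.zeros(3),
            osc_amp_g=np.zeros(3),
            hr_multiplier=0.95,
        ),
        ActivityLabel.WALKING: ActivityParams(
            gravity_vector=grav(0.0, -1.0, -0.05),
            osc_freq_hz=np.array([0.95, 1.9, 1.9]),
            osc_amp_g=np.array([0.04, 0.12, 0.05]),
            hr_multiplier=1.3,
        ),
        ActivityLabel.UPSTAIRS: ActivityParams(
            gravity_vector=grav(0.0, -0.97, -0.24),
            osc_freq_hz=np.array([0.85, 1.7, 1.7]),
            osc_amp_g=np.array([0.06, 0.20, 0.08]),
            hr_multiplier=1.5,
        ),
        ActivityLabel.DOWNSTAIRS: ActivityParams(
            gravity_vector=grav(0.0, -0.97, 0.24),
            osc_freq_hz=np.array([1.1, 2.2, 2.2]),
            osc_amp_g=np.array([0.05, 0.20, 0.10]),
            hr_multiplier=1.5,
        ),
        ActivityLabel.WORKING: ActivityParams(
            gravity_vector=grav(0.06, -1.0, -0.10),
            osc_freq_hz=np.array([0.8, 0.8, 0.8]),
            osc_amp_g=np.array([0.12, 0.03, 0.12]),
            hr_multiplier=1.2,
        ),
    }


def activity_params(
    activity: ActivityLabel, separability_activity: float = 1.0
) -> ActivityParams:
    """Activity parameters blended toward the across-activity mean.

    ``separability_activity = 1`` returns the full table entry; 0 makes
    every activity identical to the mean activity (gravity renormalized
    to unit magnitude so the static 1 g constraint is preserved).
    """
    base = _base_activity_params()
    act = base[ActivityLabel(activity)]
    s = float(separability_activity)
    if s == 1.0:
        return act
    mean_grav = np.mean([p.gravity_vector for p in base.values()], axis=0)
    mean_freq = np.mean([p.osc_freq_hz for p in base.values()], axis=0)
    mean_amp = np.mean([p.osc_amp_g for p in base.values()], axis=0)
    mean_hr = float(np.mean([p.hr_multiplier for p in base.values()]))
    grav = mean_grav + s * (act.gravity_vector - mean_grav)
    grav = grav / np.linalg.norm(grav)
    return ActivityParams(
        gravity_vector=grav,
        osc_freq_hz=mean_freq + s * (act.osc_freq_hz - mean_freq),
        osc_amp_g=mean_amp + s * (act.osc_amp_g - mean_amp),
        hr_multiplier=mean_hr + s * (act.hr_multiplier - mean_hr),
    )


def _stable_int(text: str) -> int:
    # stable across processes (unlike hash())
    return zlib.crc32(text.encode("utf-8"))


def sample_subject_params(
    subject_id: str, separability_subject: float, rng_seed: int
) -> SubjectParams:
    """Draw one subject's morphology/gait parameters.

    All inter-subject spreads scale linearly with ``separability_subject``;
    at 0 every subject receives the population-mean morphology exactly.
    Deterministic in ``(subject_id, separability_subject, rng_seed)``.
    """
    s = float(separability_subject)
    if not 0.0 <= s <= 1.0:
        raise ValueError("separability_subject must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), _stable_int(str(subject_id))]))
    hr = float(np.clip(_POP_HR_REST + s * rng.uniform(-_HR_SPREAD, _HR_SPREAD), 40.0, 180.0))
    amps = _POP_QRS_AMP * (1.0 + s * QRS_AMP_CV * rng.standard_normal((2, 5)))
    widths = _POP_QRS_WIDTH * np.exp(s * _QRS_WIDTH_CV * rng.standard_normal(5))
    offsets = _QRS_OFFSETS * (1.0 + s * _QRS_OFFSET_CV * rng.standard_normal(5))
    offsets[2] = 0.0  # R peak anchors the beat clock
    cadence = float(np.clip(_POP_CADENCE + s * _CADENCE_SPREAD * rng.standard_normal(), 1.2, 2.6))
    amp_scale = float(np.exp(s * _ACC_SCALE_SIGMA * rng.standard_normal()))
    tilt = float(s * _ORIENTATION_DEG * rng.standard_normal())
    return SubjectParams(
        subject_id=str(subject_id),
        hr_rest=hr,
        qrs_amplitudes=amps,
        qrs_widths=widths,
        cadence_hz=cadence,
        acc_amp_scale=amp_scale,
        orientation_jitter_deg=tilt,
        qrs_offsets=offsets,
    )


def generate_acc(
    subject: SubjectParams,
    activity: ActivityParams,
    duration_s: float,
    rate: float,
    noise_acc_g: float,
    rng_seed: int,
) -> tuple[SignalChannel, SignalChannel, SignalChannel]:
    """Simulate the three ACC axes for one trial.

    Each axis is the (tilt-rotated) gravity component plus a fundamental
    sinusoid at the activity/subject cadence with a 30% second harmonic,
    plus white noise.  The fundamental amplitude is calibrated so the
    oscillation's sample standard deviation equals ``osc_amp_g``.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration_s and rate must be positive")
    rng = np.random.default_rng(rng_seed)
    n = round(duration_s * rate)
    t = np.arange(n) / rate
    # sensor-tilt jitter: pitch about x plus a smaller roll about z
    rot = Rotation.from_euler(
        "xz", [subject.orientation_jitter_deg, 0.6 * subject.orientation_jitter_deg], degrees=True
    )
    gravity = rot.apply(activity.gravity_vector)
    out = []
    for axis, kind in enumerate(ACC_KINDS):
        sig = np.full(n, gravity[axis])
        amp = activity.osc_amp_g[axis] * subject.acc_amp_scale
        freq = activity.osc_freq_hz[axis]
        if amp > 0 and freq > 0:
            f = freq * subject.cadence_hz / _POP_CADENCE
            a1 = amp / _HARMONIC_STD_RATIO
            phase1, phase2 = rng.uniform(0, 2 * np.pi, 2)
            sig = sig + a1 * (
                np.sin(2 * np.pi * f * t + phase1) + 0.3 * np.sin(4 * np.pi * f * t + phase2)
            )
        if noise_acc_g > 0:
            sig = sig + noise_acc_g * rng.standard_normal(n)
        out.append(SignalChannel(kind=kind, samples=sig, rate=rate, units="g"))
    return tuple(out)


def _beat_template(subject: SubjectParams, lead: int, rate: float) -> np.ndarray:
    """One beat of lead ``lead`` sampled at ``rate``, window ±0.35 s around R."""
    half = round(0.35 * rate)
    tau = np.arange(-half, half + 1) / rate
    tpl = np.zeros_like(tau)
    for w in range(5):
        tpl += subject.qrs_amplitudes[lead, w] * np.exp(
            -0.5 * ((tau - subject.qrs_offsets[w]) / subject.qrs_widths[w]) ** 2
        )
    return tpl


def generate_ecg(
    subject: SubjectParams,
    activity: ActivityParams,
    duration_s: float,
    rate: float,
    noise_ecg: float,
    rng_seed: int,
) -> tuple[SignalChannel, SignalChannel]:
    """Simulate the two ECG leads for one trial.

    A beat train at ``hr_rest × hr_multiplier`` with Gaussian RR jitter
    (3% of the mean RR); every beat is the subject's fixed P/Q/R/S/T
    template, so morphology is constant within and across activities.
    """
    if duration_s <= 0 or rate <= 0:
        raise ValueError("duration_s and rate must be positive")
    rng = np.random.default_rng(rng_seed)
    n = round(duration_s * rate)
    hr = subject.hr_rest * activity.hr_multiplier
    rr = 60.0 / hr
    onsets = []
    t_beat = 0.5 * rr
    while t_beat < duration_s + 0.35:
        onsets.append(t_beat)
        t_beat += rr * (1.0 + _RR_JITTER_FRAC * rng.standard_normal())
    out = []
    for lead, kind in enumerate(ECG_KINDS):
        tpl = _beat_template(subject, lead, rate)
        half = (len(tpl) - 1) // 2
        sig = np.zeros(n)
        for tb in onsets:
            center = round(tb * rate)
            lo, hi = center - half, center + half + 1
            tlo, thi = max(0, lo), min(n, hi)
            if tlo < thi:
                sig[tlo:thi] += tpl[tlo - lo : thi - lo]
        if noise_ecg > 0:
            sig = sig + noise_ecg * rng.standard_normal(n)
        out.append(SignalChannel(kind=kind, samples=sig, rate=rate, units="a.u."))
    return tuple(out)


def generate_trial(
    subject: SubjectParams,
    activity_label: ActivityLabel,
    config: CohortConfig,
    rng_seed: int,
) -> Trial:
    act = activity_params(activity_label, config.separability.activity)
    acc = generate_acc(
        subject, act, config.duration_s, config.acc_rate, config.noise_acc_g, rng_seed
    )
    ecg = generate_ecg(
        subject, act, config.duration_s, config.ecg_rate, config.noise_ecg, rng_seed + 1
    )
    channels = {ch.kind: ch for ch in (*acc, *ecg)}
    return Trial(
        trial_id=f"{subject.subject_id}_{ActivityLabel(activity_label).value}",
        subject_id=subject.subject_id,
        activity=ActivityLabel(activity_label),
        channels=channels,
    )


def generate_cohort(config: CohortConfig) -> list[Trial]:
    """One trial per (subject, activity) pair; deterministic under seed."""
    trials = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        subject = sample_subject_params(subject_id, config.separability.subject, config.seed)
        for j, act in enumerate(config.activities):
            trial_seed = int(
                np.random.SeedSequence([config.seed, 1000 + i, j]).generate_state(1)[0] % (2**31)
            )
            trials.append(generate_trial(subject, act, config, trial_seed))
    return trials


# ---------------------------------------------------------------------------
# cohort directory I/O: manifest.json + one CSV per trial per modality
# ---------------------------------------------------------------------------


def save_cohort(
    trials: list[Trial],
    out_dir: str | Path,
    config: CohortConfig | None = None,
    preprocessed: bool = False,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "preprocessed": preprocessed,
        "trials": [
            {
                "trial_id": tr.trial_id,
                "subject_id": tr.subject_id,
                "activity": tr.activity.value,
                "acc_rate": tr.acc_rate,
                "ecg_rate": tr.ecg_rate,
                "units": {k.value: tr.channels[k].units for k in ChannelKind},
            }
            for tr in trials
        ],
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        cfg["activities"] = [a.value for a in config.activities]
        manifest["config"] = cfg
        manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for tr in trials:
        acc = pd.DataFrame(
            {
                "t": tr.channels[ChannelKind.ACC_X].time(),
                "x": tr.channels[ChannelKind.ACC_X].samples,
                "y": tr.channels[ChannelKind.ACC_Y].samples,
                "z": tr.channels[ChannelKind.ACC_Z].samples,
            }
        )
        acc.to_csv(out / f"{tr.trial_id}_acc.csv", index=False)
        ecg = pd.DataFrame(
            {
                "t": tr.channels[ChannelKind.ECG_1].time(),
                "ch1": tr.channels[ChannelKind.ECG_1].samples,
                "ch2": tr.channels[ChannelKind.ECG_2].samples,
            }
        )
        ecg.to_csv(out / f"{tr.trial_id}_ecg.csv", index=False)
    return out


def load_cohort(in_dir: str | Path) -> list[Trial]:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    trials = []
    for meta in manifest["trials"]:
        acc = pd.read_csv(src / f"{meta['trial_id']}_acc.csv")
        ecg = pd.read_csv(src / f"{meta['trial_id']}_ecg.csv")
        units = meta.get("units", {})
        channels = {}
        for kind, col, df, rate in [
            (ChannelKind.ACC_X, "x", acc, meta["acc_rate"]),
            (ChannelKind.ACC_Y, "y", acc, meta["acc_rate"]),
            (ChannelKind.ACC_Z, "z", acc, meta["acc_rate"]),
            (ChannelKind.ECG_1, "ch1", ecg, meta["ecg_rate"]),
            (ChannelKind.ECG_2, "ch2", ecg, meta["ecg_rate"]),
        ]:
            channels[kind] = SignalChannel(
                kind=kind,
                samples=df[col].to_numpy(),
                rate=rate,
                units=units.get(kind.value, ""),
            )
        trials.append(
            Trial(
                trial_id=meta["trial_id"],
                subject_id=meta["subject_id"],
                activity=ActivityLabel(meta["activity"]),
                channels=channels,
            )
        )
    return trials
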