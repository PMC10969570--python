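"""Synthetic six-channel inertial lifting trials.

Emulates the acquisition protocol of a sternum-mounted IMU study of manual
load lifting: each subject performs two 8-minute trials of 20 consecutive
liftings at 2.5 liftings/min, once with the squat technique (safe posture)
and once with the stoop technique (unsafe posture).  Real recordings from
that protocol are not public, so every downstream stage (segmentation,
feature extraction, statistics, classifier benchmark) is exercised on
signals produced here.

Signal model
------------
Each lifting contributes a Gaussian-windowed oscillatory burst to all six
channels (tri-axial linear acceleration in m/s^2, tri-axial angular velocity
in deg/s), superimposed on Gaussian baseline sensor noise.  The dominant
burst energy sits on the x (longitudinal/vertical) acceleration channel,
the axis along which the load travels.  Posture class enters through the
burst morphology:

* **safe (squat)** -- longer, smoother bursts carrying a single higher
  carrier frequency: a controlled, leg-driven lift.
* **unsafe (stoop)** -- shorter bursts at a lower carrier frequency with a
  half-frequency subcarrier (energy spread over two spectral lines) and
  substantially larger trunk angular velocity.  The subcarrier's amplitude
  stays below half the carrier's, so it broadens the spectrum without
  adding zero crossings or slope reversals of its own.

These choices reproduce, in expectation, the class-contrast directions a
single sternum sensor shows between squat and stoop lifting: safe liftings
have higher zero-crossing and slope-sign-change counts and a peakier
spectrum (higher spectral kurtosis/skewness, lower spectral entropy), while
unsafe liftings carry more angular-velocity amplitude and power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "SubjectProfile",
    "TrialSpec",
    "SixChannelSignal",
    "BurstParams",
    "CLASS_PARAMS",
    "generate_trial",
    "trial_components",
    "generate_cohort",
]

CHANNELS = ("ax", "ay", "az", "vx", "vy", "vz")
CLASSES = ("safe", "unsafe")

#: Relative burst gain per acceleration axis (x dominant).
ACC_GAINS = np.array([1.0, 0.30, 0.50])
#: Relative burst gain per angular-velocity axis.
VEL_GAINS = np.array([1.0, 0.70, 0.50])
#: Gyroscope baseline noise, in deg/s per m/s^2 of accelerometer noise.
VEL_NOISE_RATIO = 15.0


@dataclass(frozen=True)
class BurstParams:
    """Class-dependent morphology of one lifting burst."""

    acc_carrier_hz: float    # oscillation frequency on acceleration channels
    vel_carrier_hz: float    # oscillation frequency on gyro channels
    burst_sigma_s: float     # Gaussian window SD; burst lasts ~5 sigma
    sub_amp: float           # subcarrier amplitude relative to the carrier
    acc_amp: float           # peak acceleration amplitude, m/s^2
    vel_amp: float           # peak angular-velocity amplitude, deg/s


#: Default per-class burst morphologies (see module docstring).
CLASS_PARAMS: dict[str, BurstParams] = {
    "safe": BurstParams(
        acc_carrier_hz=7.0, vel_carrier_hz=6.0, burst_sigma_s=0.90,
        sub_amp=0.0, acc_amp=1.2, vel_amp=25.0,
    ),
    "unsafe": BurstParams(
        acc_carrier_hz=4.0, vel_carrier_hz=3.5, burst_sigma_s=0.55,
        sub_amp=0.5, acc_amp=0.85, vel_amp=45.0,
    ),
}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject heterogeneity of the simulated cohort."""

    subject_id: int
    amplitude_scale: float = 1.0   # gain on burst amplitude, > 0
    timing_jitter_sd: float = 1.0  # SD of lifting-onset jitter, s
    noise_sd: float = 0.002        # accelerometer baseline noise, m/s^2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_scale < 0:
            raise ConfigError("amplitude_scale must be >= 0")
        if self.timing_jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigError("timing_jitter_sd and noise_sd must be >= 0")


@dataclass(frozen=True)
class TrialSpec:
    """Protocol timing of one trial."""

    posture_class: str = "safe"
    n_liftings: int = 20
    lifting_frequency: float = 2.5  # liftings per minute
    duration: float = 8.0           # minutes
    sampling_rate: float = 200.0    # Hz

    def __post_init__(self) -> None:
        if self.posture_class not in CLASSES:
            raise ConfigError(f"unknown posture_class {self.posture_class!r}")
        if self.sampling_rate <= 100.0:
            raise ConfigError(
                "sampling_rate must exceed 100 Hz so a 1-50 Hz band-pass is realizable"
            )
        if self.n_liftings <= 0:
            raise ConfigError("n_liftings must be positive")
        if self.n_liftings != round(self.lifting_frequency * self.duration):
            raise ConfigError(
                f"n_liftings={self.n_liftings} inconsistent with "
                f"{self.lifting_frequency}/min x {self.duration} min"
            )

    @property
    def n_samples(self) -> int:
        return round(self.duration * 60.0 * self.sampling_rate)

    @property
    def interval_s(self) -> float:
        """Nominal spacing between consecutive lifting onsets, s."""
        return 60.0 / self.lifting_frequency


@dataclass
class SixChannelSignal:
    """One subject-trial: (n, 6) sample matrix plus metadata."""

    samples: np.ndarray            # columns ax, ay, az, vx, vy, vz
    sampling_rate: float
    subject_id: int
    posture_class: str
    lift_centers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ConfigError("samples must be an (n, 6) matrix")
        if not np.isfinite(self.samples).all():
            raise ConfigError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


# ----------------------------------------------------------------------
def _trial_rng(profile: SubjectProfile, spec: TrialSpec) -> np.random.Generator:
    # distinct stream per (subject, trial) while staying reproducible
    return np.random.default_rng([profile.rng_seed, CLASSES.index(spec.posture_class)])


def trial_components(
    profile: SubjectProfile, spec: TrialSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free burst track, additive noise and lifting centers.

    Returns ``(clean, noise, centers)`` where ``clean + noise`` is the trial
    that :func:`generate_trial` assembles, and ``centers`` holds the jittered
    burst-center sample indices (one per lifting).  Exposed separately so
    tests can count bursts and measure burst energy on the noiseless track.
    """
    rng = _trial_rng(profile, spec)
    p = CLASS_PARAMS[spec.posture_class]
    fs = spec.sampling_rate
    n = spec.n_samples
    t = np.arange(n) / fs

    clean = np.zeros((n, 6))
    centers = np.empty(spec.n_liftings)
    jitter_cap = spec.interval_s / 4.0
    for k in range(spec.n_liftings):
        jitter = rng.normal(0.0, profile.timing_jitter_sd)
        jitter = float(np.clip(jitter, -jitter_cap, jitter_cap))
        phase_a = rng.uniform(0.0, 2 * np.pi)
        phase_v = rng.uniform(0.0, 2 * np.pi)
        amp_fac = rng.uniform(0.85, 1.15)
        c = (k + 0.5) * spec.interval_s + jitter
        centers[k] = c

        sigma = p.burst_sigma_s
        lo = max(0, int((c - 4 * sigma) * fs))
        hi = min(n, int((c + 4 * sigma) * fs) + 1)
        tt = t[lo:hi] - c
        window = np.exp(-0.5 * (tt / sigma) ** 2)
        gain = profile.amplitude_scale * amp_fac

        def tone(carrier_hz: float, phase: float) -> np.ndarray:
            w = np.sin(2 * np.pi * carrier_hz * tt + phase)
            if p.sub_amp > 0:
                w = w + p.sub_amp * np.sin(np.pi * carrier_hz * tt + phase / 2)
            return window * w

        burst_a = tone(p.acc_carrier_hz, phase_a)
        burst_v = tone(p.vel_carrier_hz, phase_v)
        clean[lo:hi, 0:3] += np.outer(burst_a, ACC_GAINS) * (p.acc_amp * gain)
        clean[lo:hi, 3:6] += np.outer(burst_v, VEL_GAINS) * (p.vel_amp * gain)

        # slow trunk-tilt component (below the analysis pass-band) on the
        # antero-posterior acceleration and medio-lateral gyro axes
        tilt_sigma = 2.0 * sigma
        lo2 = max(0, int((c - 4 * tilt_sigma) * fs))
        hi2 = min(n, int((c + 4 * tilt_sigma) * fs) + 1)
        tilt = np.exp(-0.5 * ((t[lo2:hi2] - c) / tilt_sigma) ** 2)
        clean[lo2:hi2, 2] += 0.3 * p.acc_amp * gain * tilt
        clean[lo2:hi2, 4] += 0.3 * p.vel_amp * gain * tilt

    noise = rng.normal(0.0, 1.0, size=(n, 6))
    noise[:, 0:3] *= profile.noise_sd
    noise[:, 3:6] *= profile.noise_sd * VEL_NOISE_RATIO
    return clean, noise, np.round(centers * fs).astype(int)


def generate_trial(profile: SubjectProfile, spec: TrialSpec) -> SixChannelSignal:
    """Simulate one subject-trial of consecutive liftings.

    The trial contains exactly ``spec.n_liftings`` bursts centred at
    jittered multiples of the inter-lifting interval, on top of Gaussian
    baseline noise.  Deterministic given ``profile.rng_seed`` and the
    posture class.
    """
    clean, noise, centers = trial_components(profile, spec)
    return SixChannelSignal(
        samples=clean + noise,
        sampling_rate=spec.sampling_rate,
        subject_id=profile.subject_id,
        posture_class=spec.posture_class,
        lift_centers=centers,
    )


def generate_cohort(
    n_subjects: int = 15,
    cohort_seed: int = 20240576,
    *,
    sampling_rate: float = 200.0,
    duration: float = 8.0,
    lifting_frequency: float = 2.5,
) -> list[tuple[SubjectProfile, SixChannelSignal, SixChannelSignal]]:
    """Simulate a full cohort: one safe and one unsafe trial per subject.

    Per-subject burst gain, timing jitter and sensor noise are drawn
    reproducibly from ``cohort_seed``; trial seeds derive from the cohort
    seed plus the subject id, so any subject can be regenerated alone.
    """
    if n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2 (leave-one-subject-out undefined)")
    rng = np.random.default_rng(cohort_seed)
    n_lift = round(lifting_frequency * duration)
    out = []
    for sid in range(n_subjects):
        profile = SubjectProfile(
            subject_id=sid,
            amplitude_scale=float(rng.uniform(0.8, 1.2)),
            timing_jitter_sd=float(rng.uniform(0.5, 1.5)),
            noise_sd=float(rng.uniform(0.0015, 0.003)),
            rng_seed=int(cohort_seed + sid),
        )
        trials = []
        for cls in CLASSES:
            spec = TrialSpec(
                posture_class=cls,
                n_liftings=n_lift,
                lifting_frequency=lifting_frequency,
                duration=duration,
                sampling_rate=sampling_rate,
            )
            trials.append(generate_trial(profile, spec))
        out.append((profile, trials[0], trials[1]))
    return out
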