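"""Seeded synthetic resting-state EEG cohorts.

Real cohorts for this kind of study are rarely shareable, so the package
ships a generator whose spectral structure mimics what the method is
designed to detect: on a subset of "informative" electrodes, a latent
cognition score ``c`` in [0, 1] shifts a theta/alpha spectral peak
upward (6.5 Hz at the impaired end to 10.5 Hz at the normal end) and
scales a beta-band (20 Hz) oscillation, on top of a 1/f aperiodic
background and white sensor noise.  Non-informative electrodes carry
background and noise only.  The latent score maps to a MoCA-like
integer in [10, 30]; ages are drawn independently of cognition unless
an explicit confounding knob is turned.

Oscillations are realised as white noise driven through an AR(2)
resonator (pole radius 0.97), which produces a sharp, stationary
spectral peak at the pole frequency.  The 1/f background is realised by
spectral shaping of white noise so the log-log PSD slope matches the
aperiodic exponent over 2-40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import Dataset, EEGRecording, SubjectRecord

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_subject",
    "generate_cohort",
    "latent_to_score",
    "DEFAULT_INFORMATIVE",
    "DEFAULT_CHANNELS",
]

#: default montage: the 8 informative electrodes use the labels of the
#: best-performing real-cohort electrodes; the rest are common 10-10 sites.
DEFAULT_INFORMATIVE = ("P8", "PO7", "CP1", "CP2", "P6", "O2", "P4", "F4")
DEFAULT_CHANNELS = DEFAULT_INFORMATIVE + (
    "Fp1", "Fp2", "F3", "C3", "Cz", "T7", "T8", "Oz",
)

#: AR(2) resonator pole radius: close to the unit circle for a sharp peak
RESONATOR_RADIUS = 0.97


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    ``peak_lo``/``peak_hi`` are the endpoints of the cognition-driven
    theta->alpha peak shift; ``beta_gain_lo``/``beta_gain_hi`` scale the
    beta oscillation between the impaired (c=0) and normal (c=1) ends.
    ``peak_amp`` and ``background_amp`` set the standard deviation of the
    shifting resonator and of the 1/f background relative to the white
    noise floor (``noise_sd``).
    """

    n_subjects: int
    n_channels: int = 16
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    informative_channels: frozenset[str] = frozenset(DEFAULT_INFORMATIVE)
    sample_rate: float = 500.0
    duration: float = 160.0
    peak_lo: float = 6.5
    peak_hi: float = 10.5
    beta_center: float = 20.0
    beta_gain_lo: float = 0.4
    beta_gain_hi: float = 1.2
    peak_amp: float = 1.5
    background_amp: float = 1.0
    aperiodic_exponent: float = 1.0
    noise_sd: float = 1.0
    score_min: int = 10
    score_max: int = 30
    age_lo: float = 55.0
    age_hi: float = 80.0
    age_c_correlation: float = 0.0
    pd_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if not self.informative_channels <= set(self.channel_labels):
            extra = set(self.informative_channels) - set(self.channel_labels)
            raise ValueError(f"informative channels not in montage: {sorted(extra)}")
        if not (self.peak_lo <= self.peak_hi):
            raise ValueError("peak_lo must be <= peak_hi")
        if not (0 < self.peak_hi < self.sample_rate / 2):
            raise ValueError("peak_hi must lie below Nyquist")
        if self.score_min >= self.score_max:
            raise ValueError("score_min must be < score_max")
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sample_rate must be a whole sample count")
        if not (0.0 <= self.age_c_correlation <= 1.0):
            raise ValueError("age_c_correlation must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class SyntheticCohort:
    recordings: list[EEGRecording]
    subjects: list[SubjectRecord]
    latents: dict[str, float]

    def to_dataset(self) -> Dataset:
        return Dataset(
            subjects=self.subjects,
            recordings={r.subject_id: r for r in self.recordings},
        )


def latent_to_score(c: float, spec: SyntheticSpec) -> int:
    """Map latent cognition c in [0,1] to a MoCA-like integer score."""
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"latent score must be in [0, 1], got {c}")
    raw = round(spec.score_min + c * (spec.score_max - spec.score_min))
    return int(np.clip(raw, spec.score_min, spec.score_max))


def _resonator(rng: np.random.Generator, n: int, freq: float, fs: float) -> np.ndarray:
    """Unit-variance AR(2) resonance peaking at ``freq`` Hz.

    The spectral peak of an AR(2) process sits slightly below its pole
    angle (cos w_peak = cos theta (1+rho^2)/(2 rho)), so the pole angle
    is compensated to put the peak exactly at the requested frequency.
    """
    rho = RESONATOR_RADIUS
    w = 2.0 * np.pi * freq / fs
    cos_theta = np.clip(np.cos(w) * 2.0 * rho / (1.0 + rho**2), -1.0, 1.0)
    a = [1.0, -2.0 * rho * cos_theta, rho**2]
    x = sps.lfilter([1.0], a, rng.standard_normal(n))
    return x / x.std()

def _pink(rng: np.random.Generator, n: int, exponent: float, fs: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    # amplitude ~ f^(-exponent/2) gives PSD ~ f^(-exponent); flatten below
    # 0.5 Hz so the DC region stays finite
    shape = np.maximum(f, 0.5) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(W * shape, n)
    return x / x.std()


def generate_subject(
    c: float, spec: SyntheticSpec, subject_seed: int, subject_id: str = "S000"
) -> EEGRecording:
    """One subject's multichannel recording at latent cognition ``c``.

    Deterministic given ``(c, spec, subject_seed)``: channels are drawn
    in montage order from a single seeded generator.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"latent score must be in [0, 1], got {c}")
    rng = np.random.default_rng(subject_seed)
    n = spec.n_samples
    fs = spec.sample_rate
    f_peak = spec.peak_lo + c * (spec.peak_hi - spec.peak_lo)
    beta_amp = spec.beta_gain_lo + c * (spec.beta_gain_hi - spec.beta_gain_lo)
    samples = np.empty((spec.n_channels, n))
    for row, label in enumerate(spec.channel_labels):
        x = spec.background_amp * _pink(rng, n, spec.aperiodic_exponent, fs)
        x += spec.noise_sd * rng.standard_normal(n)
        if label in spec.informative_channels:
            x += spec.peak_amp * _resonator(rng, n, f_peak, fs)
            x += beta_amp * _resonator(rng, n, spec.beta_center, fs)
        samples[row] = x
    return EEGRecording(
        subject_id=subject_id,
        channel_labels=list(spec.channel_labels),
        sample_rate=fs,
        samples=samples,
    )


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """A full cohort: recordings, subject table and the latent scores.

    Latents are uniform on [0, 1]; ages uniform on [age_lo, age_hi] and
    independent of cognition unless ``age_c_correlation`` mixes in a
    cognition-dependent component (older = lower c, for confounding
    studies).  Group labels (PD / control) are assigned at the
    ``pd_fraction`` ratio independently of cognition.
    """
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    latents = rng.uniform(0.0, 1.0, n)
    age_noise = rng.uniform(0.0, 1.0, n)
    w = spec.age_c_correlation
    age_frac = (1.0 - w) * age_noise + w * (1.0 - latents)
    ages = spec.age_lo + (spec.age_hi - spec.age_lo) * age_frac
    is_pd = rng.uniform(size=n) < spec.pd_fraction
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)

    ids = [f"S{i + 1:03d}" for i in range(n)]
    recordings, subjects, latent_map = [], [], {}
    for i, sid in enumerate(ids):
        c = float(latents[i])
        recordings.append(
            generate_subject(c, spec, int(subject_seeds[i]), subject_id=sid)
        )
        subjects.append(
            SubjectRecord(
                id=sid,
                group="PD" if is_pd[i] else "control",
                age=float(np.round(ages[i], 1)),
                scores={"moca": float(latent_to_score(c, spec))},
            )
        )
        latent_map[sid] = c
    return SyntheticCohort(recordings=recordings, subjects=subjects,
                           latents=latent_map)


def effect_free(spec: SyntheticSpec) -> SyntheticSpec:
    """A copy of ``spec`` with the cognition->spectrum association removed.

    Pins the peak shift (peak_lo = peak_hi at the midpoint) and flattens
    the beta gain, so recordings carry no information about the latent
    score; downstream classification should sit at chance.
    """
    mid_peak = 0.5 * (spec.peak_lo + spec.peak_hi)
    mid_gain = 0.5 * (spec.beta_gain_lo + spec.beta_gain_hi)
    return replace(
        spec,
        peak_lo=mid_peak, peak_hi=mid_peak,
        beta_gain_lo=mid_gain, beta_gain_hi=mid_gain,
    )
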