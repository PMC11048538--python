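"""Synthetic motor-imagery EEG trials.

Generates labeled 3-channel (C3, Cz, C4) trials carrying the statistical
structure motor-imagery pipelines rely on: band-limited mu (8-13 Hz) and
beta (13-30 Hz) oscillations over a 1/f^alpha background, with
event-related desynchronisation (ERD) modelled as a multiplicative
attenuation of the rhythm on the channel contralateral to the imagined
hand (right hand -> C3, left hand -> C4).  Cz carries the rhythm at half
amplitude and is class-neutral.

The model is deliberately simple: per trial, one mu and one beta
sinusoid with frequency drawn uniformly within its band and uniform
random phase, ERD applied over the whole trial.  Temporal ERD onset
dynamics, artifacts and inter-subject variability are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

CHANNELS = ("C3", "Cz", "C4")
LABELS = ("left", "right")
#: channel attenuated by ERD for each imagined hand (contralateral cortex)
CONTRALATERAL = {"right": "C3", "left": "C4"}
IPSILATERAL = {"right": "C4", "left": "C3"}

MU_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic trial generator.

    ``erd_depth`` is the fractional attenuation applied to the
    contralateral channel's rhythm: its oscillation amplitude is
    multiplied by ``1 - erd_depth``.
    """

    duration_s: float = 4.0
    sample_rate: float = 250.0
    mu_band: tuple = MU_BAND
    beta_band: tuple = BETA_BAND
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    erd_depth: float = 0.6
    noise_amp: float = 1.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        nyq = self.sample_rate / 2.0
        for name, band in (("mu_band", self.mu_band), ("beta_band", self.beta_band)):
            lo, hi = band
            if not (0 < lo < hi < nyq):
                raise ValueError(f"{name}={band} must be strictly increasing and below "
                                 f"Nyquist ({nyq} Hz)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))


@dataclass
class EEGTrial:
    """One labeled 3-channel raw EEG segment (rows in C3, Cz, C4 order)."""

    samples: np.ndarray
    label: str
    sample_rate: float
    trial_id: str
    channel_names: tuple = CHANNELS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 3:
            raise ValueError(f"samples must be 3 x T, got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[CHANNELS.index(name)]


@dataclass
class TrialSet:
    trials: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        rates = {t.sample_rate for t in self.trials}
        lens = {t.n_samples for t in self.trials}
        if len(rates) > 1 or len(lens) > 1:
            raise ValueError("trials must share sample_rate and duration")

    def __len__(self):
        return len(self.trials)

    def __iter__(self) -> Iterator[EEGTrial]:
        return iter(self.trials)

    def class_counts(self) -> dict:
        counts = {lab: 0 for lab in LABELS}
        for t in self.trials:
            counts[t.label] += 1
        return counts

    def subset(self, labels: Sequence[str]) -> "TrialSet":
        return TrialSet([t for t in self.trials if t.label in labels], dict(self.metadata))


def _one_over_f_noise(n, exponent, rng):
    """White Gaussian noise shaped to a 1/f^alpha amplitude spectrum."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    spec = (re + 1j * im) * shape
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_trial(label: str, cfg: SynthConfig, rng: np.random.Generator,
                   trial_id: str = "trial") -> EEGTrial:
    """One synthetic trial; deterministic given (label, cfg, rng state)."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    n = cfg.n_samples
    t = np.arange(n) / cfg.sample_rate
    f_mu = rng.uniform(*cfg.mu_band)
    f_beta = rng.uniform(*cfg.beta_band)
    ph = rng.uniform(0, 2 * np.pi, size=2)
    rhythm = (cfg.mu_amp * np.sin(2 * np.pi * f_mu * t + ph[0])
              + cfg.beta_amp * np.sin(2 * np.pi * f_beta * t + ph[1]))

    gains = {IPSILATERAL[label]: 1.0,
             CONTRALATERAL[label]: 1.0 - cfg.erd_depth,
             "Cz": 0.5}
    samples = np.empty((3, n))
    for i, ch in enumerate(CHANNELS):
        noise = cfg.noise_amp * _one_over_f_noise(n, cfg.noise_exponent, rng)
        samples[i] = gains[ch] * rhythm + noise
    return EEGTrial(samples=samples, label=label, sample_rate=cfg.sample_rate,
                    trial_id=trial_id)


def generate_dataset(n_per_class: int, cfg: SynthConfig, seed: int | None = None) -> TrialSet:
    """Balanced set of 2 * n_per_class trials.

    Each trial draws from its own counter-keyed substream of the root
    seed, so enlarging ``n_per_class`` never reshuffles earlier trials.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    root = cfg.seed if seed is None else seed
    trials = []
    for i in range(n_per_class):
        for ci, label in enumerate(LABELS):
            ss = np.random.SeedSequence(entropy=root, spawn_key=(ci, i))
            rng = np.random.default_rng(ss)
            trials.append(generate_trial(label, cfg, rng,
                                         trial_id=f"synth-{label}-{i:04d}"))
    meta = {"seed": root, "n_per_class": n_per_class,
            "config": {k: v for k, v in vars(cfg).items()}}
    return TrialSet(trials, meta)


def band_power(trial: EEGTrial, band: tuple) -> np.ndarray:
    """Mean Welch-periodogram power per channel within ``band`` (3-vector)."""
    lo, hi = band
    if not (0 < lo < hi < trial.sample_rate / 2):
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < Nyquist "
                         f"({trial.sample_rate / 2} Hz)")
    nper = min(trial.n_samples, 512)
    freqs, pxx = sps.welch(trial.samples, fs=trial.sample_rate, nperseg=nper, axis=1)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} selects no frequency bins")
    return pxx[:, sel].mean(axis=1)


def train_test_sets(cfg: SynthConfig, n_train_per_class: int, n_test_per_class: int,
                    seed: int) -> tuple:
    """Disjoint train/test TrialSets from independent substreams."""
    train = generate_dataset(n_train_per_class, cfg, seed=seed)
    test = generate_dataset(n_test_per_class, cfg, seed=seed + 1_000_003)
    for t in test.trials:
        t.trial_id = "test-" + t.trial_id
    return train, test
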