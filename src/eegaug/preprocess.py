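"""Trial -> 32x32 time-frequency image pipeline.

Each 3-channel trial is band-pass filtered to 0.5-40 Hz, each channel is
turned into an STFT log-magnitude map (128-sample Hann windows, 75 %
overlap, 512 FFT points), cropped to the 0.5-40 Hz rows, resized to
11 x 33, and the three channel maps are stacked vertically (C3 on top,
then Cz, then C4) into a 33 x 33 map which is resized to 32 x 32 and
min-max normalised to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from .synth import CHANNELS, LABELS, EEGTrial, TrialSet


@dataclass(frozen=True)
class STFTParams:
    window_len: int = 128
    overlap_frac: float = 0.75
    n_fft: int = 512
    window_fn: str = "hann"
    band: tuple = (0.5, 40.0)
    per_channel_shape: tuple = (11, 33)
    output_shape: tuple = (32, 32)
    log_power: bool = True
    pixel_range: tuple = (0.0, 1.0)

    def __post_init__(self):
        if self.window_len > self.n_fft:
            raise ValueError("window_len must not exceed n_fft")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must be in [0, 1)")

    @property
    def hop(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap_frac)))

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.window_len) // self.hop + 1


@dataclass
class SpectrogramImage:
    """32x32 grayscale time-frequency image with class label."""

    pixels: np.ndarray
    label: str
    source_id: str
    kind: str = "real"  # "real" | "generated"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.kind not in ("real", "generated"):
            raise ValueError(f"kind must be 'real' or 'generated', got {self.kind!r}")


@dataclass
class ImageSet:
    images: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {im.pixels.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"inhomogeneous image shapes: {shapes}")

    def __len__(self):
        return len(self.images)

    def __iter__(self) -> Iterator[SpectrogramImage]:
        return iter(self.images)

    def class_counts(self) -> dict:
        counts = {lab: 0 for lab in LABELS}
        for im in self.images:
            counts[im.label] += 1
        return counts

    def pixel_array(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images])

    def label_array(self) -> np.ndarray:
        return np.array([LABELS.index(im.label) for im in self.images])

    def subset(self, idx) -> "ImageSet":
        return ImageSet([self.images[i] for i in idx], dict(self.metadata))


def _apply_freq_gain(trial: EEGTrial, gain: np.ndarray) -> EEGTrial:
    spec = np.fft.rfft(trial.samples, axis=1)
    filtered = np.fft.irfft(spec * gain, n=trial.n_samples, axis=1)
    return EEGTrial(samples=filtered, label=trial.label,
                    sample_rate=trial.sample_rate, trial_id=trial.trial_id)


def _raised_cosine_ramp(freqs, start, stop):
    """0 below start, 1 above stop, half-cosine in between."""
    ramp = np.clip((freqs - start) / max(stop - start, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * ramp))


def bandpass(trial: EEGTrial, lo: float, hi: float,
             trans_lo: float | None = None, trans_hi: float = 5.0) -> EEGTrial:
    """Zero-phase frequency-domain band-pass with raised-cosine edges.

    Spectral-domain filtering avoids the start/end transients IIR
    filters leave on short epochs; transitions span ``trans_lo`` Hz
    below ``lo`` (default lo/2) and ``trans_hi`` Hz above ``hi``.
    """
    nyq = trial.sample_rate / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"hi={hi} Hz is at or above Nyquist ({nyq} Hz)")
    if trans_lo is None:
        trans_lo = lo / 2.0
    freqs = np.fft.rfftfreq(trial.n_samples, 1.0 / trial.sample_rate)
    gain = (_raised_cosine_ramp(freqs, lo - trans_lo, lo)
            * (1.0 - _raised_cosine_ramp(freqs, hi, hi + trans_hi)))
    return _apply_freq_gain(trial, gain)


def notch(trial: EEGTrial, f0: float = 50.0, width: float = 2.0) -> EEGTrial:
    """Zero-phase frequency-domain notch: full suppression at ``f0``,
    tapering back to unit gain at ``f0 +/- width`` Hz."""
    nyq = trial.sample_rate / 2.0
    if not 0 < f0 < nyq:
        raise ValueError(f"f0={f0} Hz must lie in (0, {nyq}) Hz")
    freqs = np.fft.rfftfreq(trial.n_samples, 1.0 / trial.sample_rate)
    bump = 0.5 * (1.0 + np.cos(np.pi * np.clip((freqs - f0) / width, -1, 1)))
    bump[np.abs(freqs - f0) >= width] = 0.0
    return _apply_freq_gain(trial, 1.0 - bump)


def stft_magnitude(x: np.ndarray, fs: float, p: STFTParams) -> np.ndarray:
    """Magnitude (or log1p-magnitude) STFT of a 1-D signal.

    Frames start at multiples of the hop with no padding, so
    ``n_frames = (T - window_len) // hop + 1``; row k corresponds to
    ``k * fs / n_fft`` Hz.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("stft_magnitude expects a 1-D signal")
    if x.size < p.window_len:
        raise ValueError(f"signal of length {x.size} is shorter than the "
                         f"{p.window_len}-sample analysis window")
    hop = p.hop
    n_frames = p.n_frames(x.size)
    win = sps.get_window(p.window_fn, p.window_len, fftbins=True)
    idx = hop * np.arange(n_frames)[:, None] + np.arange(p.window_len)[None, :]
    frames = x[idx] * win
    spec = np.abs(np.fft.rfft(frames, n=p.n_fft, axis=1)).T  # (n_fft//2+1, n_frames)
    if p.log_power:
        spec = np.log1p(spec)
    return spec


def band_crop(spec: np.ndarray, fs: float, n_fft: int, band: tuple) -> np.ndarray:
    """Retain contiguous rows k with lo <= k*fs/n_fft <= hi."""
    spec = np.asarray(spec)
    expected = n_fft // 2 + 1
    if spec.shape[0] != expected:
        raise ValueError(f"spec must have {expected} rows, got {spec.shape[0]}")
    lo, hi = band
    k_lo = int(math.ceil(lo * n_fft / fs))
    k_hi = int(math.floor(hi * n_fft / fs))
    k_hi = min(k_hi, expected - 1)
    if k_lo > k_hi:
        raise ValueError(f"band {band} selects no rows at fs={fs}, n_fft={n_fft}")
    return spec[k_lo:k_hi + 1]


def crop_rows(fs: float, n_fft: int, band: tuple) -> tuple:
    """(first, last) retained bin indices for ``band`` — the row->Hz map."""
    lo, hi = band
    k_lo = int(math.ceil(lo * n_fft / fs))
    k_hi = min(int(math.floor(hi * n_fft / fs)), n_fft // 2)
    return k_lo, k_hi


def _lin_weights(n_src: int, n_dst: int) -> np.ndarray:
    """Endpoint-aligned linear interpolation matrix (n_dst x n_src)."""
    w = np.zeros((n_dst, n_src))
    if n_dst == 1:
        w[0, :] = 1.0 / n_src
        return w
    pos = np.linspace(0.0, n_src - 1.0, n_dst)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_src - 1)
    frac = pos - lo
    w[np.arange(n_dst), lo] += 1.0 - frac
    w[np.arange(n_dst), hi] += frac
    return w


def resize_map(spec: np.ndarray, target: tuple) -> np.ndarray:
    """Separable bilinear resize with endpoint alignment.

    Constant input stays constant and a same-shape target is the
    identity.
    """
    spec = np.asarray(spec, dtype=float)
    rows, cols = target
    if rows < 1 or cols < 1:
        raise ValueError(f"degenerate target shape {target}")
    if spec.shape[0] < 2 or spec.shape[1] < 2:
        raise ValueError(f"source {spec.shape} too small to interpolate")
    if spec.shape == (rows, cols):
        return spec.copy()
    wr = _lin_weights(spec.shape[0], rows)
    wc = _lin_weights(spec.shape[1], cols)
    return wr @ spec @ wc.T


def normalize_image(img: np.ndarray, pixel_range=(0.0, 1.0)) -> np.ndarray:
    """Per-image min-max scaling; a constant image maps to the midpoint."""
    lo, hi = pixel_range
    mn, mx = img.min(), img.max()
    if mx - mn < 1e-12:
        return np.full_like(img, (lo + hi) / 2.0)
    return lo + (img - mn) * (hi - lo) / (mx - mn)


def stack_and_normalize(c3: np.ndarray, cz: np.ndarray, c4: np.ndarray,
                        p: STFTParams, label: str = "left", source_id: str = "",
                        kind: str = "real") -> SpectrogramImage:
    """Stack per-channel maps vertically (C3, Cz, C4) into a 32x32 image."""
    maps = {"C3": np.asarray(c3), "Cz": np.asarray(cz), "C4": np.asarray(c4)}
    for name, m in maps.items():
        if m.shape != tuple(p.per_channel_shape):
            raise ValueError(f"channel {name} map has shape {m.shape}, expected "
                             f"{tuple(p.per_channel_shape)}")
    stacked = np.vstack([maps["C3"], maps["Cz"], maps["C4"]])
    resized = resize_map(stacked, p.output_shape)
    pixels = normalize_image(resized, p.pixel_range)
    return SpectrogramImage(pixels=pixels, label=label, source_id=source_id,
                            kind=kind)


def preprocess_trial(trial: EEGTrial, p: STFTParams = STFTParams(),
                     apply_notch: bool = False) -> SpectrogramImage:
    """Full pipeline: filter -> per-channel STFT -> crop -> resize -> stack."""
    try:
        t = notch(trial) if apply_notch else trial
        t = bandpass(t, p.band[0], p.band[1])
        channel_maps = []
        for i in range(3):
            spec = stft_magnitude(t.samples[i], t.sample_rate, p)
            spec = band_crop(spec, t.sample_rate, p.n_fft, p.band)
            channel_maps.append(resize_map(spec, p.per_channel_shape))
        image = stack_and_normalize(*channel_maps, p, label=trial.label,
                                    source_id=trial.trial_id, kind="real")
    except ValueError as e:
        raise ValueError(f"trial {trial.trial_id!r}: {e}") from e
    return image


def preprocess_dataset(ts: TrialSet, p: STFTParams = STFTParams(),
                       apply_notch: bool = False) -> ImageSet:
    images = [preprocess_trial(t, p, apply_notch) for t in ts]
    return ImageSet(images, {"stft": vars(p) | {}, "n_trials": len(ts)})


def row_band_map(p: STFTParams = STFTParams(), fs: float = 250.0,
                 bands: dict | None = None) -> dict:
    """Which final-image rows carry each channel's mu/beta content.

    Traces the crop -> per-channel resize -> stack -> final resize chain
    and returns ``{channel: {band_name: sorted row indices}}`` over the
    32 output rows.
    """
    if bands is None:
        bands = {"mu": (8.0, 13.0), "beta": (13.0, 30.0)}
    k_lo, k_hi = crop_rows(fs, p.n_fft, p.band)
    n_crop = k_hi - k_lo + 1
    pc_rows = p.per_channel_shape[0]
    n_stack = 3 * pc_rows
    out_rows = p.output_shape[0]

    # frequency of each per-channel row (endpoint-aligned resize)
    pc_pos = np.linspace(0, n_crop - 1, pc_rows)
    pc_freq = (k_lo + pc_pos) * fs / p.n_fft

    # final row -> position in the stacked map (endpoint-aligned)
    stack_pos = np.linspace(0, n_stack - 1, out_rows)
    result = {ch: {b: [] for b in bands} for ch in CHANNELS}
    for r, pos in enumerate(stack_pos):
        src = int(round(pos))
        ch = CHANNELS[min(src // pc_rows, 2)]
        freq = pc_freq[min(src % pc_rows, pc_rows - 1)]
        for bname, (blo, bhi) in bands.items():
            if blo <= freq <= bhi:
                result[ch][bname].append(r)
    return result
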