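"""Shared fixtures: small synthetic datasets and an EDF+ fixture writer."""

import numpy as np
import pytest

from eegaug.preprocess import STFTParams, preprocess_dataset
from eegaug.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig()


@pytest.fixture(scope="session")
def small_trials(synth_cfg):
    """20 trials (10 per class), defaults, fixed seed."""
    return generate_dataset(10, synth_cfg, seed=11)


@pytest.fixture(scope="session")
def small_images(small_trials):
    return preprocess_dataset(small_trials, STFTParams())


def _pad(text, n):
    b = str(text).encode("ascii")
    if len(b) > n:
        raise ValueError(f"field too long: {text!r}")
    return b + b" " * (n - len(b))


def write_minimal_edf(path, data, sfreq, events, ch_names=("C3", "Cz", "C4")):
    """Write a small synthetic EDF+C file with cue annotations.

    ``data`` is (n_channels, T) in arbitrary units; ``events`` is a list
    of (onset_seconds, code_string) pairs, e.g. ("769" = left cue,
    "770" = right cue in the BCI IV 2b dialect).  Synthetic test fixture
    only — not a general-purpose EDF writer.
    """
    data = np.asarray(data, dtype=float)
    n_ch, T = data.shape
    sfreq = int(sfreq)
    assert T % sfreq == 0, "fixture wants whole seconds"
    n_rec = T // sfreq
    ann_bytes = 60  # per-record annotation payload (30 2-byte samples)

    # scale each channel into int16 against a fixed physical range
    phys_lo, phys_hi = -1000.0, 1000.0
    dig_lo, dig_hi = -32768, 32767
    scaled = np.clip((data - phys_lo) / (phys_hi - phys_lo), 0, 1)
    dig = (scaled * (dig_hi - dig_lo) + dig_lo).astype("<i2")

    ns = n_ch + 1
    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate 01-JAN-2024 X X X", 80),
        _pad("01.01.24", 8), _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8), _pad("EDF+C", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(ns), 4),
    ])
    labels = [_pad(n, 16) for n in ch_names] + [_pad("EDF Annotations", 16)]
    transducer = [_pad("", 80)] * ns
    dim = [_pad("uV", 8)] * n_ch + [_pad("", 8)]
    pmin = [_pad("-1000", 8)] * n_ch + [_pad("-1", 8)]
    pmax = [_pad("1000", 8)] * n_ch + [_pad("1", 8)]
    dmin = [_pad("-32768", 8)] * ns
    dmax = [_pad("32767", 8)] * ns
    prefilter = [_pad("", 80)] * ns
    nsamp = [_pad(str(sfreq), 8)] * n_ch + [_pad(str(ann_bytes // 2), 8)]
    reserved = [_pad("", 32)] * ns
    header += b"".join(b"".join(f) for f in
                       (labels, transducer, dim, pmin, pmax, dmin, dmax,
                        prefilter, nsamp, reserved))

    by_record = {}
    for onset, code in events:
        by_record.setdefault(int(onset), []).append((onset, code))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            for ch in range(n_ch):
                fh.write(dig[ch, rec * sfreq:(rec + 1) * sfreq].tobytes())
            tal = f"+{rec}\x14\x14\x00".encode()
            for onset, code in by_record.get(rec, []):
                tal += f"+{onset:g}\x14{code}\x14\x00".encode()
            if len(tal) > ann_bytes:
                raise ValueError("too many events in one record for fixture")
            fh.write(tal + b"\x00" * (ann_bytes - len(tal)))
    return path
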