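"""Reading real EEG recordings and persisting pipeline artifacts.

Real recordings (BCI Competition IV 2b ships as GDF; EDF also accepted)
are read through mne; cue annotations are mapped to left/right labels by
a single event-code table.  Image sets are stored as 8-bit grayscale
PNGs with a CSV manifest (optionally plus a lossless float archive);
trial sets and model checkpoints use numpy archives with JSON metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import ImageSet, SpectrogramImage
from .synth import CHANNELS, EEGTrial, TrialSet

logger = logging.getLogger(__name__)

#: cue annotation -> class label (BCI IV 2b dialect; one place to fix drift)
EVENT_LABELS = {
    "769": "left", "770": "right",
    "cue left": "left", "cue right": "right",
    "class1, left hand": "left",
    "class2, right hand": "right",
}


def read_trials(path, window=(0.0, 4.0)) -> TrialSet:
    """One labeled trial per cue event, cropped to ``window`` (s after cue)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".gdf":
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")

    picks = []
    for want in CHANNELS:
        matches = [ch for ch in raw.ch_names
                   if ch == want or ch.split(":")[-1].strip() == want]
        if not matches:
            raise ValueError(f"recording {path.name} lacks required channel "
                             f"{want!r} (has {raw.ch_names})")
        picks.append(matches[0])
    data = raw.get_data(picks=picks)
    sfreq = float(raw.info["sfreq"])
    n_len = int(round((window[1] - window[0]) * sfreq))

    trials, skipped = [], 0
    for i, ann in enumerate(raw.annotations):
        label = EVENT_LABELS.get(str(ann["description"]).strip().lower())
        if label is None:
            skipped += 1
            continue
        start = int(round((ann["onset"] + window[0]) * sfreq))
        if start < 0 or start + n_len > data.shape[1]:
            skipped += 1
            continue
        trials.append(EEGTrial(samples=data[:, start:start + n_len],
                               label=label, sample_rate=sfreq,
                               trial_id=f"{path.stem}-ev{i:04d}"))
    if skipped:
        logger.info("read_trials(%s): skipped %d events (unknown code or out of "
                    "bounds)", path.name, skipped)
    return TrialSet(trials, {"source": str(path), "window": list(window),
                             "skipped_events": skipped})


# -- trial sets ---------------------------------------------------------

def write_trialset(ts: TrialSet, path) -> Path:
    path = Path(path)
    arrays = {f"trial_{i:05d}": t.samples for i, t in enumerate(ts)}
    meta = {"trials": [{"trial_id": t.trial_id, "label": t.label,
                        "sample_rate": t.sample_rate} for t in ts],
            "metadata": _jsonable(ts.metadata)}
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def read_trialset(path) -> TrialSet:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        trials = [EEGTrial(samples=z[f"trial_{i:05d}"], label=m["label"],
                           sample_rate=m["sample_rate"], trial_id=m["trial_id"])
                  for i, m in enumerate(meta["trials"])]
    return TrialSet(trials, meta.get("metadata", {}))


# -- image sets ---------------------------------------------------------

def write_image_set(images: ImageSet, out_dir, lossless: bool = False) -> Path:
    """PNG per image + manifest.csv; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        fname = f"img_{i:05d}.png"
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / fname)
        rows.append({"filename": fname, "label": im.label, "kind": im.kind,
                     "source_id": im.source_id})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["filename", "label", "kind", "source_id"]) \
        .to_csv(manifest, index=False)
    if lossless:
        np.savez_compressed(out_dir / "pixels.npz",
                            pixels=np.stack([im.pixels for im in images])
                            if len(images) else np.zeros((0, 0, 0)))
    return manifest


def read_image_set(in_dir) -> ImageSet:
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    df = pd.read_csv(manifest, dtype=str).fillna("")
    lossless = None
    npz_path = in_dir / "pixels.npz"
    if npz_path.exists():
        with np.load(npz_path) as z:
            lossless = z["pixels"]
    images = []
    for i, row in df.iterrows():
        if lossless is not None and i < len(lossless):
            pixels = lossless[i]
        else:
            fpath = in_dir / row["filename"]
            if not fpath.exists():
                raise FileNotFoundError(f"manifest references missing file "
                                        f"{row['filename']!r}")
            pixels = np.asarray(Image.open(fpath), dtype=float) / 255.0
        images.append(SpectrogramImage(pixels=pixels, label=row["label"],
                                       source_id=row["source_id"],
                                       kind=row["kind"] or "real"))
    return ImageSet(images, {"source": str(in_dir)})


# -- checkpoints --------------------------------------------------------

def save_checkpoint(module, path, meta: dict | None = None) -> Path:
    path = Path(path)
    state = module.state_dict()
    arrays = {f"param::{k}": v for k, v in state.items()}
    arrays["_meta"] = np.frombuffer(
        json.dumps(_jsonable(meta or {})).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_checkpoint(module, path) -> dict:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    module.load_state_dict(state)
    return meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
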