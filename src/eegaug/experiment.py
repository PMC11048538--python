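"""Augmentation-benefit protocol.

For each seed: synthesise disjoint train/test trial sets, preprocess to
images, train the conditional WGAN-GP on the *training* images only,
generate a pool of synthetic images, mix them with the real training set
at each requested ratio, train a fresh classifier per mixture, and
evaluate every classifier on the same held-out real test images.  The
report carries one accuracy per (ratio, seed, variant) cell plus per-
ratio aggregates and deltas against the real-only (ratio 0) baseline.

Also provides a quantitative stand-in for visual comparison of real and
generated spectrograms: mean pixel intensity inside the image rows that
carry each channel's mu/beta band, and the between-class difference of
contralateral-channel mu intensity, whose sign is the class signature
event-related desynchronisation imprints on the images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gan import (DiscriminatorSpec, GANTrainConfig, GeneratorSpec,
                  generate_samples, train_dcgan_gp)
from .preprocess import ImageSet, STFTParams, preprocess_dataset, row_band_map
from .resnet import ClassifierTrainConfig, evaluate, train_classifier
from .synth import LABELS, SynthConfig, train_test_sets


@dataclass(frozen=True)
class MixSpec:
    ratios: tuple = (0.0, 0.5, 1.0, 1.5)
    seeds: tuple = (0,)
    variants: tuple = ("resnet10",)

    def __post_init__(self):
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be non-negative")
        if list(self.ratios) != sorted(self.ratios):
            raise ValueError("ratios must be sorted ascending")
        if len(self.seeds) < 1:
            raise ValueError("need at least one seed")


@dataclass
class ExperimentReport:
    cells: list = field(default_factory=list)  # dicts: ratio, seed, variant, accuracy
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells)

    def aggregate(self) -> pd.DataFrame:
        """Mean / min / max accuracy per (variant, ratio) + delta vs ratio 0."""
        df = self.to_frame()
        agg = (df.groupby(["variant", "ratio"])["accuracy"]
                 .agg(["mean", "min", "max"]).reset_index())
        base = {v: g.loc[g["ratio"] == 0.0, "mean"].iloc[0] if (g["ratio"] == 0.0).any()
                else np.nan
                for v, g in agg.groupby("variant")}
        agg["delta_vs_real_only"] = agg.apply(
            lambda r: r["mean"] - base[r["variant"]], axis=1)
        return agg

    def to_dict(self) -> dict:
        return {"cells": self.cells,
                "aggregate": self.aggregate().to_dict(orient="records"),
                "provenance": self.provenance}


def mix_datasets(real: ImageSet, generated: ImageSet, ratio: float,
                 rng: np.random.Generator) -> ImageSet:
    """All real images + round(ratio * |real|) generated ones, class-balanced.

    Generated images are drawn without replacement, allocated to classes
    in proportion to the real set (largest-remainder rounding so the
    total count is exact); the combined order is shuffled.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    n_real = len(real)
    n_gen = int(round(ratio * n_real))
    if n_gen == 0:
        return ImageSet(list(real.images), dict(real.metadata))

    real_counts = real.class_counts()
    quota = {}
    exact = {lab: n_gen * real_counts[lab] / n_real for lab in LABELS}
    for lab in LABELS:
        quota[lab] = int(np.floor(exact[lab]))
    rem = n_gen - sum(quota.values())
    for lab in sorted(LABELS, key=lambda l: exact[l] - quota[l], reverse=True)[:rem]:
        quota[lab] += 1

    pool = {lab: [im for im in generated if im.label == lab] for lab in LABELS}
    chosen = []
    for lab in LABELS:
        if len(pool[lab]) < quota[lab]:
            raise ValueError(f"generated pool has {len(pool[lab])} {lab!r} images, "
                             f"need {quota[lab]} (shortfall "
                             f"{quota[lab] - len(pool[lab])})")
        idx = rng.choice(len(pool[lab]), size=quota[lab], replace=False)
        chosen.extend(pool[lab][i] for i in idx)

    mixed = list(real.images) + chosen
    order = rng.permutation(len(mixed))
    return ImageSet([mixed[i] for i in order],
                    {"ratio": ratio, "n_real": n_real, "n_generated": n_gen})


def band_power_comparison(real: ImageSet, generated: ImageSet,
                          rbm: dict | None = None) -> dict:
    """Mu/beta-row intensity summary for real vs generated image sets.

    Returns a dict with a tidy ``table`` (set, class, channel, band, mean
    intensity), the per-channel between-class contralateral mu
    differences ``mean(left) - mean(right)`` for each set, and whether
    their signs agree between the real and generated sets on both C3
    (expected > 0: right-hand imagery attenuates C3) and C4 (expected
    < 0).
    """
    if len(real) == 0 or len(generated) == 0:
        raise ValueError("image sets must be non-empty")
    if rbm is None:
        rbm = row_band_map()
    rows = []
    diffs = {}
    for set_name, imset in (("real", real), ("generated", generated)):
        pix = imset.pixel_array()
        labs = imset.label_array()
        means = {}
        for ch, bands in rbm.items():
            for bname, ridx in bands.items():
                if not ridx:
                    continue
                for ci, lab in enumerate(LABELS):
                    sel = pix[labs == ci]
                    val = float(sel[:, ridx, :].mean()) if sel.size else float("nan")
                    means[(ch, bname, lab)] = val
                    rows.append({"set": set_name, "class": lab, "channel": ch,
                                 "band": bname, "mean_intensity": val})
        diffs[set_name] = {
            ch: means.get((ch, "mu", "left"), np.nan)
                - means.get((ch, "mu", "right"), np.nan)
            for ch in ("C3", "C4")}
    agreement = all(
        np.sign(diffs["real"][ch]) == np.sign(diffs["generated"][ch])
        and diffs["real"][ch] != 0
        for ch in ("C3", "C4"))
    return {"table": pd.DataFrame(rows),
            "contralateral_mu_diff": diffs,
            "sign_agreement": bool(agreement)}


def run_augmentation_experiment(mix: MixSpec,
                                synth_cfg: SynthConfig = SynthConfig(),
                                gan_cfg: GANTrainConfig = GANTrainConfig(),
                                clf_cfg: ClassifierTrainConfig = ClassifierTrainConfig(),
                                n_train_per_class: int = 200,
                                n_test_per_class: int = 160,
                                stft: STFTParams = STFTParams(),
                                gspec: GeneratorSpec = GeneratorSpec(),
                                dspec: DiscriminatorSpec = DiscriminatorSpec(),
                                gen_pool_factor: float = 2.0,
                                progress=None) -> ExperimentReport:
    """Full protocol across seeds, ratios and classifier variants."""
    report = ExperimentReport(provenance={
        "ratios": list(mix.ratios), "seeds": list(mix.seeds),
        "variants": list(mix.variants),
        "n_train_per_class": n_train_per_class,
        "n_test_per_class": n_test_per_class,
        "gan_iterations": gan_cfg.iterations,
        "clf_epochs": clf_cfg.epochs,
    })
    for seed in mix.seeds:
        train_ts, test_ts = train_test_sets(synth_cfg, n_train_per_class,
                                            n_test_per_class, seed)
        train_ids = {t.trial_id for t in train_ts}
        test_ids = {t.trial_id for t in test_ts}
        if train_ids & test_ids:
            raise RuntimeError(f"seed {seed}: train/test trial id overlap")
        train_imgs = preprocess_dataset(train_ts, stft)
        test_imgs = preprocess_dataset(test_ts, stft)

        max_ratio = max(mix.ratios)
        gen_pool = None
        if max_ratio > 0:
            gcfg = GANTrainConfig(**{**vars(gan_cfg), "seed": seed})
            try:
                gen, _, _ = train_dcgan_gp(train_imgs, gspec, dspec, gcfg)
            except FloatingPointError as e:
                raise RuntimeError(f"stage GAN-training failed at seed {seed}: {e}")
            n_pool = int(np.ceil(gen_pool_factor * max_ratio * n_train_per_class))
            gen_pool = generate_samples(gen, max(n_pool, 1), seed=seed + 777)

        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(42,)))
        for ratio in mix.ratios:
            mixed = (ImageSet(list(train_imgs.images))
                     if ratio == 0 else mix_datasets(train_imgs, gen_pool, ratio, rng))
            for variant in mix.variants:
                ccfg = ClassifierTrainConfig(**{**vars(clf_cfg), "seed": seed})
                try:
                    model = train_classifier(mixed, ccfg, variant=variant)
                    acc = evaluate(model, test_imgs).accuracy
                except (ValueError, FloatingPointError) as e:
                    raise RuntimeError(f"stage classifier ({variant}, ratio {ratio}) "
                                       f"failed at seed {seed}: {e}")
                report.cells.append({"ratio": float(ratio), "seed": int(seed),
                                     "variant": variant, "accuracy": float(acc)})
                if progress is not None:
                    progress(report.cells[-1])
    return report
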