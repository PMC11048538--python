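"""Class-conditional DCGAN trained with the WGAN-GP objective.

The generator maps a 100-d standard-normal latent (concatenated with a
2-d one-hot class label) through a wide fully connected layer, a reshape
to an 8x8x128 map, and two stride-2 transposed convolutions up to a
single-channel 32x32 image in [-1, 1] (tanh).  Layer normalisation and
Leaky ReLU (slope 0.2) follow the hidden stages.

The critic is a Wasserstein critic: three stride-2 convolutions
(1->64->128->256, kernel 4) with layer normalisation after all but the
first, Leaky ReLU activations, and a linear head emitting one unbounded
score — no sigmoid anywhere.  The class label enters as one constant
extra input plane (+1 / -1).

Losses (minimisation form):

    L_G = -E[D(G(z))]
    L_D =  E[D(G(z))] - E[D(x)] + lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]

with xhat = eps * x + (1 - eps) * G(z), eps ~ U[0, 1] per sample.  Each
outer iteration runs ``n_critic`` critic updates followed by one
generator update, with Adam (lr 2e-4, beta1 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, grad, no_grad
from .preprocess import ImageSet, SpectrogramImage
from .synth import LABELS


@dataclass(frozen=True)
class GeneratorSpec:
    latent_dim: int = 100
    label_dim: int = 2
    fc_out_shape: tuple = (128, 8, 8)  # channels, height, width
    upsample_channels: tuple = (64, 1)
    kernel: int = 4
    lrelu_slope: float = 0.2
    conditional: bool = True


@dataclass(frozen=True)
class DiscriminatorSpec:
    conv_channels: tuple = (64, 128, 256)
    kernel: int = 4
    lrelu_slope: float = 0.2
    conditional: bool = True
    input_shape: tuple = (32, 32)


@dataclass(frozen=True)
class GANTrainConfig:
    gp_weight: float = 10.0
    n_critic: int = 5
    batch_size: int = 64
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    iterations: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        if self.gp_weight < 0:
            raise ValueError("gp_weight must be >= 0")
        if min(self.batch_size, self.iterations) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, iterations and learning_rate must be positive")


@dataclass
class LatentSample:
    """Batch of latent vectors z ~ N(0, I) with integer labels + one-hot."""

    z: np.ndarray           # (m, latent_dim)
    labels: np.ndarray      # (m,) ints in {0, 1}
    onehot: np.ndarray      # (m, 2)


@dataclass
class InterpolatedBatch:
    images: np.ndarray      # (m, 1, 32, 32)
    eps: np.ndarray         # (m,) in [0, 1]
    labels: np.ndarray      # (m,)


@dataclass
class TrainHistory:
    critic_loss: list = field(default_factory=list)
    gen_loss: list = field(default_factory=list)
    grad_penalty: list = field(default_factory=list)
    wasserstein: list = field(default_factory=list)

    @property
    def critic_updates(self) -> int:
        return len(self.critic_loss)

    @property
    def generator_updates(self) -> int:
        return len(self.gen_loss)


class Generator(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        c0, h0, w0 = spec.fc_out_shape
        n_in = spec.latent_dim + (spec.label_dim if spec.conditional else 0)
        self.fc = nn.Linear(n_in, c0 * h0 * w0, rng)
        self.ln0 = nn.LayerNorm(c0)
        c1, c2 = spec.upsample_channels
        self.up1 = nn.ConvTranspose2d(c0, c1, spec.kernel, 2, 1, rng)
        self.ln1 = nn.LayerNorm(c1)
        self.up2 = nn.ConvTranspose2d(c1, c2, spec.kernel, 2, 1, rng)

    def __call__(self, z, onehot=None):
        spec = self.spec
        z = ad.as_tensor(np.asarray(z, dtype=np.float32))
        if z.shape[-1] != spec.latent_dim:
            raise ValueError(f"latent dim {z.shape[-1]} != {spec.latent_dim}")
        if spec.conditional:
            if onehot is None:
                raise ValueError("conditional generator needs labels")
            z = ad.concat([z, ad.as_tensor(np.asarray(onehot, dtype=np.float32))],
                          axis=1)
        c0, h0, w0 = spec.fc_out_shape
        h = ad.leaky_relu(self.ln0(self.fc(z).reshape((-1, c0, h0, w0))),
                          spec.lrelu_slope)
        h = ad.leaky_relu(self.ln1(self.up1(h)), spec.lrelu_slope)
        return ad.tanh(self.up2(h))


class Critic(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        c1, c2, c3 = spec.conv_channels
        cin = 2 if spec.conditional else 1
        k = spec.kernel
        self.conv1 = nn.Conv2d(cin, c1, k, 2, 1, rng)
        self.conv2 = nn.Conv2d(c1, c2, k, 2, 1, rng)
        self.ln2 = nn.LayerNorm(c2)
        self.conv3 = nn.Conv2d(c2, c3, k, 2, 1, rng)
        self.ln3 = nn.LayerNorm(c3)
        h, w = spec.input_shape
        self.head = nn.Linear(c3 * (h // 8) * (w // 8), 1, rng)

    def __call__(self, images, labels=None):
        spec = self.spec
        x = ad.as_tensor(images)
        if x.ndim == 3:
            x = x.reshape((x.shape[0], 1) + tuple(x.shape[1:]))
        if tuple(x.shape[2:]) != tuple(spec.input_shape) or x.shape[1] != 1:
            raise ValueError(f"critic expects (m, 1, {spec.input_shape[0]}, "
                             f"{spec.input_shape[1]}) images, got {x.shape}")
        if spec.conditional:
            if labels is None:
                raise ValueError("conditional critic needs labels")
            plane = (2.0 * np.asarray(labels, dtype=np.float32) - 1.0)
            plane = np.broadcast_to(plane[:, None, None, None],
                                    (x.shape[0], 1) + tuple(spec.input_shape)).copy()
            x = ad.concat([x, Tensor(plane)], axis=1)
        s = spec.lrelu_slope
        h = ad.leaky_relu(self.conv1(x), s)
        h = ad.leaky_relu(self.ln2(self.conv2(h)), s)
        h = ad.leaky_relu(self.ln3(self.conv3(h)), s)
        score = self.head(h.reshape((h.shape[0], -1)))
        return score.reshape((h.shape[0],))


def build_generator(spec: GeneratorSpec, seed: int) -> Generator:
    return Generator(spec, np.random.default_rng(np.random.SeedSequence(seed)))


def build_critic(spec: DiscriminatorSpec, seed: int) -> Critic:
    return Critic(spec, np.random.default_rng(np.random.SeedSequence(seed)))


def sample_latent(m: int, labels, rng: np.random.Generator,
                  latent_dim: int = 100) -> LatentSample:
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = np.array([LABELS.index(l) for l in labels])
    if labels.shape != (m,):
        raise ValueError(f"need {m} labels, got shape {labels.shape}")
    z = rng.standard_normal((m, latent_dim)).astype(np.float32)
    onehot = np.eye(2, dtype=np.float32)[labels]
    return LatentSample(z=z, labels=labels, onehot=onehot)


def interpolate(real: np.ndarray, fake: np.ndarray, rng: np.random.Generator,
                labels=None) -> InterpolatedBatch:
    """Per-sample convex combinations eps*real + (1-eps)*fake, eps ~ U[0,1]."""
    real = np.asarray(real)
    fake = np.asarray(fake)
    if real.shape != fake.shape:
        raise ValueError(f"batch shape mismatch: {real.shape} vs {fake.shape}")
    m = real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=m)
    shaped = eps.reshape((m,) + (1,) * (real.ndim - 1)).astype(real.dtype)
    images = shaped * real + (1.0 - shaped) * fake
    return InterpolatedBatch(images=images, eps=eps,
                             labels=None if labels is None else np.asarray(labels))


def gradient_penalty(critic: Critic, xhat, labels=None, gp_weight: float = 10.0):
    """lambda * E[(||grad_x D(x)||_2 - 1)^2] on the interpolated batch.

    Returned as a differentiable scalar Tensor whose graph reaches the
    critic parameters (double backpropagation).
    """
    if gp_weight < 0:
        raise ValueError("gp_weight must be >= 0")
    if isinstance(xhat, InterpolatedBatch):
        labels = xhat.labels if labels is None else labels
        xhat = xhat.images
    x = Tensor(np.asarray(xhat), requires_grad=True)
    scores = critic(x, labels)
    g = grad(scores.sum(), x, create_graph=True)
    if not np.all(np.isfinite(g.data)):
        raise FloatingPointError("non-finite critic input gradients")
    sq = (g * g).sum(axis=tuple(range(1, g.ndim)))
    norm = sq ** 0.5
    return gp_weight * ((norm - 1.0) ** 2).mean()


def generator_loss(fake_scores):
    """-mean(D(G(z)))."""
    s = ad.as_tensor(fake_scores)
    if s.size == 0:
        raise ValueError("empty score vector")
    return -s.mean()


def discriminator_loss(real_scores, fake_scores, gp=0.0):
    """mean(fake) - mean(real) + gp  (the quantity the critic minimises)."""
    r, f = ad.as_tensor(real_scores), ad.as_tensor(fake_scores)
    if r.size == 0 or f.size == 0:
        raise ValueError("empty score vector")
    return f.mean() - r.mean() + ad.as_tensor(gp)


def _to_gan_range(images: ImageSet) -> tuple:
    """ImageSet pixels in [0,1] -> (n,1,32,32) float32 in [-1,1] plus labels."""
    x = images.pixel_array().astype(np.float32)
    x = 2.0 * x - 1.0
    return x[:, None, :, :], images.label_array()


def train_dcgan_gp(data: ImageSet, gspec: GeneratorSpec = GeneratorSpec(),
                   dspec: DiscriminatorSpec = DiscriminatorSpec(),
                   cfg: GANTrainConfig = GANTrainConfig(),
                   callback=None) -> tuple:
    """Adversarial training loop; returns (generator, critic, history).

    Per outer iteration: ``cfg.n_critic`` critic updates (fresh real
    minibatch, fresh latents, interpolation, penalty, Adam step), then
    one generator update.  Fully reproducible from ``cfg.seed``.
    """
    if len(data) == 0:
        raise ValueError("empty training set")
    x_all, y_all = _to_gan_range(data)
    if len(set(y_all.tolist())) < 2:
        raise ValueError("training data must contain both classes")

    ss = np.random.SeedSequence(cfg.seed)
    s_ginit, s_dinit, s_loop = ss.spawn(3)
    gen = Generator(gspec, np.random.default_rng(s_ginit))
    critic = Critic(dspec, np.random.default_rng(s_dinit))
    rng = np.random.default_rng(s_loop)

    g_params = gen.param_tensors()
    d_params = critic.param_tensors()
    opt_g = nn.Adam(g_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = nn.Adam(d_params, cfg.learning_rate, cfg.adam_beta1, cfg.adam_beta2)
    hist = TrainHistory()
    n = x_all.shape[0]
    m = cfg.batch_size

    for it in range(cfg.iterations):
        for _ in range(cfg.n_critic):
            idx = rng.choice(n, size=m, replace=(n < m))
            real, labels = x_all[idx], y_all[idx]
            lat = sample_latent(m, labels, rng, gspec.latent_dim)
            with no_grad():
                fake = gen(lat.z, lat.onehot).data
            xhat = interpolate(real, fake, rng, labels)
            gp = gradient_penalty(critic, xhat, gp_weight=cfg.gp_weight)
            # one fused forward for real+fake halves the conv overhead
            scores = critic(np.concatenate([real, fake]),
                            np.concatenate([labels, labels]))
            sr, sf = scores[:m], scores[m:]
            loss_d = discriminator_loss(sr, sf, gp)
            if not np.isfinite(loss_d.item()):
                raise FloatingPointError(f"non-finite critic loss at iteration {it}")
            opt_d.step(grad(loss_d, d_params))
            hist.critic_loss.append(loss_d.item())
            hist.grad_penalty.append(gp.item())
            hist.wasserstein.append(float(sr.data.mean() - sf.data.mean()))

        lat = sample_latent(m, rng.integers(0, 2, size=m), rng, gspec.latent_dim)
        fake = gen(lat.z, lat.onehot)
        loss_g = generator_loss(critic(fake, lat.labels))
        if not np.isfinite(loss_g.item()):
            raise FloatingPointError(f"non-finite generator loss at iteration {it}")
        opt_g.step(grad(loss_g, g_params))
        hist.gen_loss.append(loss_g.item())
        if callback is not None:
            callback(it, hist)
    return gen, critic, hist


def generate_samples(gen: Generator, n_per_class: int, seed: int,
                     batch: int = 64) -> ImageSet:
    """2 * n_per_class labeled images, pixels mapped back to [0, 1]."""
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = np.repeat(np.arange(2), n_per_class)
    images = []
    with no_grad():
        for start in range(0, labels.size, batch):
            lab = labels[start:start + batch]
            lat = sample_latent(lab.size, lab, rng, gen.spec.latent_dim)
            out = gen(lat.z, lat.onehot).data[:, 0]
            pix = np.clip((out + 1.0) / 2.0, 0.0, 1.0)
            for j in range(lab.size):
                images.append(SpectrogramImage(
                    pixels=pix[j].astype(float), label=LABELS[lab[j]],
                    source_id=f"gen-{LABELS[lab[j]]}-{start + j:05d}",
                    kind="generated"))
    return ImageSet(images, {"seed": seed, "n_per_class": n_per_class})
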