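"""The three networks of the scalp-to-intracranial translation model.

* **Encoder** E: strided temporal convolutions (instance norm + leaky ReLU)
  over the scalp segment, flattened into two dense heads producing the mean
  and standard deviation of the Gaussian latent posterior (z = mu + eps*sigma
  by the reparameterization trick).
* **Generator** G: the latent code is projected by a dense layer onto a
  coarse temporal grid over the intracranial sensor axis, then refined by a
  stack of spatially-adaptive-denormalization (SPADE) residual blocks
  interleaved with x2 temporal upsampling — each block's scale/shift
  modulation (gamma, beta) is predicted from the scalp segment downsampled to
  the stage's temporal resolution — followed by two LSTM layers over the L
  time steps, a time-distributed dense layer and a tanh bound.
* **Discriminator** D: a Markovian (patch) discriminator of strided temporal
  convolutions whose output is one realness score per intracranial sensor
  (patch size 1 x Mbar); intermediate feature maps are exposed for the
  feature-matching loss.

All forward passes are deterministic given parameters and inputs.  Activation
layout is (batch, channels, time, sensors); segments enter as (time, sensors)
arrays and are lifted to a single channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, astensor
from ._modules import LSTM, ConvTime, Dense, InstanceNorm, Module, sensor_norm

__all__ = [
    "ArchitectureConfig",
    "PatchScores",
    "Encoder",
    "Generator",
    "Discriminator",
    "SpadeBlock",
    "SpadeResNet",
    "reparameterize",
    "spade_modulate",
    "sample_unit_norm_latent",
]

ABLATIONS = ("full", "no_encoder", "no_spade_resnet")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shapes and depths of encoder, generator and discriminator.

    The segment geometry (L, M, Mbar) and the latent dimension Z=256 follow
    the reference setup; layer depths and filter counts are free parameters
    of the architecture family and default to a configuration that keeps the
    temporal shape algebra consistent: the encoder halves the time axis
    ``encoder_layers`` times, the generator starts at ``L / 2**generator_stages``
    and doubles back up to L, and the discriminator reaches a single time
    step before its final (un-normalized, un-activated) convolution.
    """

    L: int = 64
    M: int = 20
    M_bar: int = 12
    latent_dim: int = 256              # Z
    encoder_layers: int = 4            # I_E stride-2 conv layers
    encoder_filter_len: int = 5        # l_e
    encoder_base_filters: int = 16     # C_e, doubling per layer
    generator_stages: int = 4          # I_up SPADE-ResNet + upsample stages
    generator_base_filters: int = 16   # channels of the last stage
    lstm_hidden: int = 64
    discriminator_layers: int = 4      # I_D conv layers in total
    discriminator_filter_len: int = 5  # l_d
    discriminator_base_filters: int = 16
    leaky_slope: float = 0.2
    spade_embed_filters: int = 8
    spade_kernel: int = 3
    ablation: str = "full"

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"ablation must be one of {ABLATIONS}")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.L % (2**self.encoder_layers) or self.L // 2**self.encoder_layers < 1:
            raise ValueError(
                f"L={self.L} must be divisible by 2^encoder_layers={2**self.encoder_layers}"
            )
        if self.L % (2**self.generator_stages):
            raise ValueError(
                f"L={self.L} must be divisible by 2^generator_stages={2**self.generator_stages}"
            )
        if self.L % (2 ** (self.discriminator_layers - 1)):
            raise ValueError("L must be divisible by 2^(discriminator_layers - 1)")

    @classmethod
    def tiny(cls, **overrides) -> "ArchitectureConfig":
        """A reduced-width configuration for fast desk-scale experiments."""
        base = dict(M=8, M_bar=4, latent_dim=16, encoder_layers=3,
                    encoder_filter_len=5, encoder_base_filters=4,
                    generator_stages=2, generator_base_filters=8,
                    lstm_hidden=16, discriminator_layers=3,
                    discriminator_base_filters=8, spade_embed_filters=4)
        base.update(overrides)
        return cls(**base)

    @property
    def generator_widths(self) -> list[int]:
        return [self.generator_base_filters * 2 ** (self.generator_stages - 1 - i)
                for i in range(self.generator_stages)]


@dataclass
class PatchScores:
    """Discriminator output for one segment: (1, Mbar) per-sensor realness
    scores and the intermediate feature maps (one per layer)."""

    scores: np.ndarray
    feature_maps: list[np.ndarray]


# ---------------------------------------------------------------------------
# functional pieces


def reparameterize(mu, sigma, epsilon):
    """z = mu + epsilon (.) sigma, elementwise."""
    mu_t, sigma_t, eps_t = astensor(mu), astensor(sigma), astensor(epsilon)
    if not (mu_t.shape == sigma_t.shape == eps_t.shape):
        raise ValueError(
            f"mu/sigma/epsilon shapes differ: {mu_t.shape}, {sigma_t.shape}, {eps_t.shape}"
        )
    out = mu_t + eps_t * sigma_t
    if any(isinstance(v, Tensor) for v in (mu, sigma, epsilon)):
        return out
    return out.data


def spade_modulate(gamma, beta, normalized_activation):
    """The denormalization step itself: gamma x A + beta, elementwise."""
    g, b, a = astensor(gamma), astensor(beta), astensor(normalized_activation)
    if not (g.shape == b.shape == a.shape):
        raise ValueError("gamma, beta and activation must be conformable")
    out = g * a + b
    if any(isinstance(v, Tensor) for v in (gamma, beta, normalized_activation)):
        return out
    return out.data


def sample_unit_norm_latent(rng: np.random.Generator, batch: int, dim: int) -> np.ndarray:
    """Normalized Gaussian latent for the encoder-free ablation: standard
    normal draws rescaled to unit Euclidean norm per sample."""
    z = rng.standard_normal((batch, dim))
    return z / np.linalg.norm(z, axis=1, keepdims=True)


def _lift(x) -> Tensor:
    """(L, M) or (B, L, M) array/Tensor -> (B, 1, L, M) Tensor."""
    t = astensor(x)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
    else:
        raise ValueError(f"expected (L, M) or (batch, L, M), got shape {t.shape}")
    return t


# ---------------------------------------------------------------------------
# encoder


class Encoder(Module):
    """Variational encoder: scalp segment -> (mu, sigma) of the latent posterior.

    The sigma head outputs log-variance; sigma = exp(logvar / 2) guarantees
    strict positivity.
    """

    def __init__(self, arch: ArchitectureConfig, rng: np.random.Generator):
        self.arch = arch
        self.convs, self.norms = [], []
        c_in = 1
        for i in range(arch.encoder_layers):
            c_out = arch.encoder_base_filters * 2**i
            self.convs.append(ConvTime(c_in, c_out, arch.encoder_filter_len, rng, stride=2))
            self.norms.append(InstanceNorm(c_out))
            c_in = c_out
        flat = c_in * (arch.L // 2**arch.encoder_layers) * arch.M
        self.fc_mu = Dense(flat, arch.latent_dim, rng)
        self.fc_logvar = Dense(flat, arch.latent_dim, rng)

    def __call__(self, x) -> tuple[Tensor, Tensor]:
        h = _lift(x)
        if h.shape[2:] != (self.arch.L, self.arch.M):
            raise ValueError(
                f"encoder expects segments of shape ({self.arch.L}, {self.arch.M}), "
                f"got {h.shape[2:]}"
            )
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h)).leaky_relu(self.arch.leaky_slope)
        h = h.reshape(h.shape[0], -1)
        mu = self.fc_mu(h)
        sigma = (self.fc_logvar(h) * 0.5).exp()
        return mu, sigma

    def encode(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Numpy-facing forward pass (no graph kept)."""
        mu, sigma = self(np.asarray(x, float))
        if np.asarray(x).ndim == 2:
            return mu.data[0], sigma.data[0]
        return mu.data, sigma.data


# ---------------------------------------------------------------------------
# SPADE generator


class SpadeBlock(Module):
    """Spatially-adaptive denormalization conditioned on the scalp segment.

    The activation is normalized per (channel, sensor) over batch and time
    (batch-normalization style, keeping the sensor axis distinct); the scalp
    condition — average-pooled to the activation's temporal length — is
    projected from M scalp sensors onto the Mbar activation columns, embedded
    by a convolution, and mapped to per-element gamma and beta.
    """

    def __init__(self, channels: int, arch: ArchitectureConfig, rng: np.random.Generator):
        self.arch = arch
        from ._modules import _param  # sensor-axis projection weight

        self.sensor_proj = _param(rng, (arch.M, arch.M_bar), arch.M, arch.M_bar)
        k, e = arch.spade_kernel, arch.spade_embed_filters
        self.embed = ConvTime(1, e, k, rng)
        self.to_gamma = ConvTime(e, channels, k, rng)
        self.to_beta = ConvTime(e, channels, k, rng)

    def _modulation(self, condition: Tensor, length: int) -> tuple[Tensor, Tensor]:
        factor = condition.shape[2] // length
        cond = condition.avgpool_time(factor) if factor > 1 else condition
        if cond.shape[2] != length:
            raise ValueError(
                f"condition temporal length {condition.shape[2]} cannot be pooled to {length}"
            )
        b, c, l, m = cond.shape
        proj = (cond.reshape(b * c * l, m) @ self.sensor_proj).reshape(b, c, l, -1)
        shared = self.embed(proj).relu()
        return self.to_gamma(shared), self.to_beta(shared)

    def __call__(self, activation: Tensor, condition: Tensor) -> Tensor:
        gamma, beta = self._modulation(condition, activation.shape[2])
        return spade_modulate(gamma, beta, sensor_norm(activation))


class SpadeResNet(Module):
    """Residual block of two (SPADE -> tanh -> conv) units.

    The skip path is the identity when input and output channel counts match;
    otherwise it is a SPADE-based projection (SPADE -> 1x1 conv) to the output
    width.
    """

    def __init__(self, c_in: int, c_out: int, arch: ArchitectureConfig,
                 rng: np.random.Generator):
        c_mid = min(c_in, c_out)
        self.spade1 = SpadeBlock(c_in, arch, rng)
        self.conv1 = ConvTime(c_in, c_mid, 3, rng)
        self.spade2 = SpadeBlock(c_mid, arch, rng)
        self.conv2 = ConvTime(c_mid, c_out, 3, rng)
        if c_in != c_out:
            self.spade_skip = SpadeBlock(c_in, arch, rng)
            self.conv_skip = ConvTime(c_in, c_out, 1, rng, bias=False)
        else:
            self.spade_skip = self.conv_skip = None

    def __call__(self, x: Tensor, condition: Tensor) -> Tensor:
        h = self.conv1(self.spade1(x, condition).tanh())
        h = self.conv2(self.spade2(h, condition).tanh())
        if self.conv_skip is not None:
            skip = self.conv_skip(self.spade_skip(x, condition))
        else:
            skip = x
        return skip + h


class PlainStage(Module):
    """Convolutional replacement of the SPADE ResNet used by the
    'no_spade_resnet' ablation (ignores the condition)."""

    def __init__(self, c_in: int, c_out: int, arch: ArchitectureConfig,
                 rng: np.random.Generator):
        self.conv = ConvTime(c_in, c_out, 3, rng)
        self.norm = InstanceNorm(c_out)
        self.slope = arch.leaky_slope

    def __call__(self, x: Tensor, condition: Tensor) -> Tensor:
        return self.norm(self.conv(x)).leaky_relu(self.slope)


class Generator(Module):
    """SPADE-ResNet + LSTM generator: (scalp segment, latent code) -> estimated
    intracranial segment in (-1, 1)."""

    def __init__(self, arch: ArchitectureConfig, rng: np.random.Generator):
        self.arch = arch
        widths = arch.generator_widths
        self.L0 = arch.L // 2**arch.generator_stages
        self.c0 = widths[0]
        self.fc_z = Dense(arch.latent_dim, self.c0 * self.L0 * arch.M_bar, rng)
        stage_cls = PlainStage if arch.ablation == "no_spade_resnet" else SpadeResNet
        self.stages, self.up_convs = [], []
        c_in = self.c0
        for c_out in widths:
            self.stages.append(stage_cls(c_in, c_out, arch, rng))
            self.up_convs.append(ConvTime(c_out, c_out, 3, rng))
            c_in = c_out
        self.lstm1 = LSTM(widths[-1] * arch.M_bar, arch.lstm_hidden, rng)
        self.lstm2 = LSTM(arch.lstm_hidden, arch.lstm_hidden, rng)
        self.head = Dense(arch.lstm_hidden, arch.M_bar, rng)

    def __call__(self, x, z) -> Tensor:
        cond = _lift(x)
        if cond.shape[2:] != (self.arch.L, self.arch.M):
            raise ValueError(
                f"generator expects scalp segments ({self.arch.L}, {self.arch.M}), "
                f"got {cond.shape[2:]}"
            )
        zt = astensor(z)
        if zt.ndim == 1:
            zt = zt.reshape(1, -1)
        if zt.shape[1] != self.arch.latent_dim:
            raise ValueError(f"latent dimension {zt.shape[1]} != {self.arch.latent_dim}")
        if zt.shape[0] != cond.shape[0]:
            raise ValueError("batch sizes of scalp input and latent code differ")
        b = cond.shape[0]
        h = self.fc_z(zt).reshape(b, self.c0, self.L0, self.arch.M_bar)
        for stage, up in zip(self.stages, self.up_convs):
            h = stage(h, cond)
            h = up(h.upsample_time(2))
        # (B, C, L, Mbar) -> (B, L, C*Mbar) for the recurrent tail
        h = h.transpose(0, 2, 1, 3).reshape(b, self.arch.L, -1)
        h = self.lstm2(self.lstm1(h))
        return self.head(h).tanh()  # time-distributed dense, bounded output

    def generate(self, x, z) -> np.ndarray:
        """Numpy-facing forward pass: returns (L, Mbar) or (B, L, Mbar)."""
        out = self(np.asarray(x, float), np.asarray(z, float))
        if np.asarray(x).ndim == 2:
            return out.data[0]
        return out.data


# ---------------------------------------------------------------------------
# patch discriminator


class Discriminator(Module):
    """Markovian discriminator emitting one score per intracranial sensor.

    All but the last convolution use stride 2 on the time axis with instance
    norm and leaky ReLU; the final convolution spans the remaining time steps
    and has no normalization or activation, leaving unbounded scores of patch
    size 1 x Mbar.
    """

    def __init__(self, arch: ArchitectureConfig, rng: np.random.Generator):
        self.arch = arch
        self.convs, self.norms = [], []
        c_in = 1
        for i in range(arch.discriminator_layers - 1):
            c_out = arch.discriminator_base_filters * 2**i
            self.convs.append(ConvTime(c_in, c_out, arch.discriminator_filter_len, rng,
                                       stride=2))
            self.norms.append(InstanceNorm(c_out))
            c_in = c_out
        final_len = arch.L // 2 ** (arch.discriminator_layers - 1)
        self.final = ConvTime(c_in, 1, final_len, rng, stride=1, padding="valid")

    def __call__(self, y) -> tuple[Tensor, list[Tensor]]:
        h = _lift(y)
        if h.shape[2:] != (self.arch.L, self.arch.M_bar):
            raise ValueError(
                f"discriminator expects segments ({self.arch.L}, {self.arch.M_bar}), "
                f"got {h.shape[2:]}"
            )
        features = []
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h)).leaky_relu(self.arch.leaky_slope)
            features.append(h)
        out = self.final(h)  # (B, 1, 1, Mbar), no norm/activation
        features.append(out)
        scores = out.reshape(out.shape[0], 1, self.arch.M_bar)
        return scores, features

    def discriminate(self, y) -> PatchScores:
        """Numpy-facing pass for one segment (L, Mbar) -> PatchScores."""
        arr = np.asarray(y, float)
        if arr.ndim != 2:
            raise ValueError(f"expected one (L, Mbar) segment, got shape {arr.shape}")
        scores, features = self(arr)
        return PatchScores(scores=scores.data[0], feature_maps=[f.data[0] for f in features])
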