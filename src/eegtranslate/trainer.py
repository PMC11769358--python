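"""Joint adversarial training of encoder, generator and discriminator.

One model is trained per subject.  Each batch performs two alternating
updates: the discriminator minimizes the two-sided hinge loss on (real,
detached-estimated) intracranial segments, then the encoder+generator
minimize the composite loss (adversarial hinge + KL + L1 reconstruction +
feature matching) with a fresh latent noise draw per sample.  The
discriminator update never touches encoder/generator parameters and vice
versa (separate optimizers over disjoint parameter sets).

The training trajectory is a pure function of the configuration seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor
from .networks import (
    ArchitectureConfig,
    Discriminator,
    Encoder,
    Generator,
    reparameterize,
    sample_unit_norm_latent,
)
from .objectives import (
    LossWeights,
    feature_matching_loss,
    generator_total_loss,
    hinge_d_loss,
    hinge_g_loss,
    kl_loss,
    l1_loss,
)
from .segment_store import IntracranialSegment, ScalpSegment

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "TranslationModel",
    "TrainingDivergedError",
    "build_model",
    "train_subject",
    "train_cohort",
    "translate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 200
    batch_size: int = 16
    learning_rate_g: float = 2e-4
    learning_rate_d: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    validation_fraction: float = 0.0   # > 0 enables early stopping on val L1
    early_stop_patience: int | None = None
    log_every: int = 0                 # epochs between INFO log lines; 0 = silent


@dataclass
class TrainingHistory:
    """Per-epoch loss records (means over batches)."""

    d_loss: list = field(default_factory=list)
    g_hinge: list = field(default_factory=list)
    kl: list = field(default_factory=list)
    l1: list = field(default_factory=list)
    fm: list = field(default_factory=list)
    g_total: list = field(default_factory=list)
    val_l1: list = field(default_factory=list)

    def append_epoch(self, means: dict) -> None:
        for key, val in means.items():
            getattr(self, key).append(float(val))

    @property
    def n_epochs(self) -> int:
        return len(self.g_total)


@dataclass
class TranslationModel:
    """Trained parameters of the translation triplet plus its architecture."""

    encoder: Encoder | None
    generator: Generator
    discriminator: Discriminator
    arch: ArchitectureConfig


def build_model(arch: ArchitectureConfig, seed: int | np.random.SeedSequence = 0
                ) -> TranslationModel:
    """Freshly initialized (untrained) model; deterministic in the seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    enc = None if arch.ablation == "no_encoder" else Encoder(arch, rngs[0])
    return TranslationModel(enc, Generator(arch, rngs[1]), Discriminator(arch, rngs[2]), arch)


def _stack_segments(segments, arch: ArchitectureConfig):
    if not segments:
        raise ValueError("empty segment list")
    xs = np.stack([s.scalp.samples for s in segments])
    ys = np.stack([s.intracranial.samples for s in segments])
    if xs.shape[1:] != (arch.L, arch.M) or ys.shape[1:] != (arch.L, arch.M_bar):
        raise ValueError(
            f"segments of shape {xs.shape[1:]}/{ys.shape[1:]} do not match the architecture "
            f"({arch.L}, {arch.M})/({arch.L}, {arch.M_bar})"
        )
    return xs, ys


def _latent(model: TranslationModel, xb: np.ndarray, rng: np.random.Generator):
    """Fresh per-sample latent draw; returns (z, mu, sigma) with graph."""
    b = xb.shape[0]
    if model.encoder is None:
        return Tensor(sample_unit_norm_latent(rng, b, model.arch.latent_dim)), None, None
    mu, sigma = model.encoder(xb)
    eps = rng.standard_normal((b, model.arch.latent_dim))
    return reparameterize(mu, sigma, Tensor(eps)), mu, sigma


def _d_step(model, opt_d, xb, yb, rng):
    """Discriminator update on (real, detached estimated) segments."""
    z, _, _ = _latent(model, xb, rng)
    y_fake = model.generator(xb, z)
    s_real, _ = model.discriminator(yb)
    s_fake, _ = model.discriminator(y_fake.data)  # detached: no generator gradient
    loss = hinge_d_loss(s_real, s_fake)
    opt_d.zero_grad()
    loss.backward()
    opt_d.step()
    return float(loss.data)


def _g_step(model, opt_g, xb, yb, rng, weights: LossWeights):
    """Encoder+generator update against the current discriminator."""
    z, mu, sigma = _latent(model, xb, rng)
    y_fake = model.generator(xb, z)
    s_fake, f_fake = model.discriminator(y_fake)
    _, f_real = model.discriminator(yb)
    gh = hinge_g_loss(s_fake)
    l1 = l1_loss(Tensor(yb), y_fake)
    fm = feature_matching_loss([Tensor(f.data) for f in f_real], f_fake)
    kl = kl_loss(mu, sigma) if mu is not None else Tensor(0.0)
    total = generator_total_loss(gh, kl, l1, fm, weights)
    opt_g.zero_grad()
    total.backward()
    opt_g.step()
    return {"g_hinge": float(gh.data), "kl": float(kl.data), "l1": float(l1.data),
            "fm": float(fm.data), "g_total": float(total.data)}


def train_subject(segments, arch: ArchitectureConfig, cfg: TrainingConfig
                  ) -> tuple[TranslationModel, TrainingHistory]:
    """Train one translation model on one subject's paired segments."""
    xs, ys = _stack_segments(segments, arch)
    ss = np.random.SeedSequence(cfg.seed)
    init_seq, train_seq, split_seq = ss.spawn(3)
    model = build_model(arch, init_seq)
    rng = np.random.default_rng(train_seq)

    n_val = int(round(cfg.validation_fraction * len(xs)))
    if n_val:
        order = np.random.default_rng(split_seq).permutation(len(xs))
        val_idx, train_idx = order[:n_val], order[n_val:]
        xv, yv = xs[val_idx], ys[val_idx]
        xs, ys = xs[train_idx], ys[train_idx]

    params_g = model.generator.parameters() + (model.encoder.parameters()
                                               if model.encoder else [])
    opt_g = Adam(params_g, lr=cfg.learning_rate_g, betas=cfg.adam_betas)
    opt_d = Adam(model.discriminator.parameters(), lr=cfg.learning_rate_d,
                 betas=cfg.adam_betas)

    history = TrainingHistory()
    best_val, since_best = np.inf, 0
    n = len(xs)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        sums = {k: 0.0 for k in ("d_loss", "g_hinge", "kl", "l1", "fm", "g_total")}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = xs[idx], ys[idx]
            try:
                sums["d_loss"] += _d_step(model, opt_d, xb, yb, rng)
                g_losses = _g_step(model, opt_g, xb, yb, rng, cfg.loss_weights)
            except (ValueError, FloatingPointError) as err:
                raise TrainingDivergedError(
                    f"numerical failure at epoch {epoch}, batch {n_batches}: {err}"
                ) from err
            for key, val in g_losses.items():
                sums[key] += val
            n_batches += 1
            if not all(np.isfinite(v) for v in sums.values()):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches - 1}"
                )
        means = {k: v / n_batches for k, v in sums.items()}
        if n_val:
            est = translate(model, xv, mode="mean")
            means_val = float(np.mean(np.abs(yv - est)))
            history.val_l1.append(means_val)
            if means_val < best_val - 1e-6:
                best_val, since_best = means_val, 0
            else:
                since_best += 1
        history.append_epoch({k: means[k] for k in sums})
        if cfg.log_every and (epoch % cfg.log_every == 0 or epoch == cfg.epochs - 1):
            logger.info("epoch %d: D=%.4f Gh=%.4f KL=%.4f L1=%.4f FM=%.4f G=%.4f",
                        epoch, means["d_loss"], means["g_hinge"], means["kl"],
                        means["l1"], means["fm"], means["g_total"])
        if (n_val and cfg.early_stop_patience is not None
                and since_best > cfg.early_stop_patience):
            logger.info("early stop at epoch %d (no val-L1 improvement)", epoch)
            break
    return model, history


def train_cohort(cohort, arch: ArchitectureConfig, cfg: TrainingConfig,
                 ) -> tuple[dict, dict]:
    """One independently trained model per subject; per-subject seeds are
    deterministic offsets of the master seed.  Returns (models, histories)."""
    models, histories = {}, {}
    for i, rec in enumerate(cohort.subjects):
        sub_seed = int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31))
        sub_cfg = TrainingConfig(**{**asdict_config(cfg), "seed": sub_seed})
        try:
            models[rec.subject_id], histories[rec.subject_id] = train_subject(
                rec.segments, arch, sub_cfg)
        except Exception as err:
            raise RuntimeError(f"training failed for subject {rec.subject_id}") from err
        logger.info("trained subject %s (%d segments)", rec.subject_id, len(rec.segments))
    return models, histories


def asdict_config(cfg: TrainingConfig) -> dict:
    d = asdict(cfg)
    d["loss_weights"] = cfg.loss_weights
    d["adam_betas"] = tuple(cfg.adam_betas)
    return d


def translate(model: TranslationModel, X, mode: str = "mean",
              rng: np.random.Generator | None = None):
    """Map scalp input to estimated intracranial output.

    ``mode='mean'`` uses epsilon = 0 (z = mu), deterministic; ``mode='sample'``
    draws epsilon ~ N(0, I) from ``rng``.  For encoder-free models the latent
    is unit-norm Gaussian noise from ``rng`` (a fixed default seed if omitted,
    so repeated calls agree).  Accepts a ScalpSegment (returns an
    IntracranialSegment with provenance 'estimated'), an (L, M) array or a
    batch (n, L, M) array (returns arrays).
    """
    if mode not in ("mean", "sample"):
        raise ValueError("mode must be 'mean' or 'sample'")
    single_segment = isinstance(X, ScalpSegment)
    arr = X.samples if single_segment else np.asarray(X, dtype=float)
    batched = arr.ndim == 3
    xb = arr if batched else arr[None]
    rng = rng if rng is not None else np.random.default_rng(0)

    if model.encoder is None:
        z = sample_unit_norm_latent(rng, xb.shape[0], model.arch.latent_dim)
    else:
        mu, sigma = model.encoder.encode(xb)
        if mode == "sample":
            z = mu + rng.standard_normal(mu.shape) * sigma
        else:
            z = mu
    out = model.generator.generate(xb, z)
    if single_segment:
        return IntracranialSegment(out[0], provenance="estimated")
    return out if batched else out[0]


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: TranslationModel, path) -> Path:
    """Single-file checkpoint: architecture JSON + all parameter arrays,
    keyed ``encoder.<name>`` / ``generator.<name>`` / ``discriminator.<name>``."""
    path = Path(path)
    payload = {"__arch__": np.bytes_(json.dumps(asdict(model.arch)))}
    parts = {"generator": model.generator, "discriminator": model.discriminator}
    if model.encoder is not None:
        parts["encoder"] = model.encoder
    for prefix, net in parts.items():
        for name, arr in net.state_dict().items():
            payload[f"{prefix}.{name}"] = arr
    np.savez(path, **payload)
    return path


def load_model(path) -> TranslationModel:
    with np.load(Path(path)) as data:
        arch = ArchitectureConfig(**json.loads(bytes(data["__arch__"]).decode()))
        model = build_model(arch, seed=0)
        for prefix, net in (("encoder", model.encoder),
                            ("generator", model.generator),
                            ("discriminator", model.discriminator)):
            if net is None:
                continue
            state = {key[len(prefix) + 1:]: data[key] for key in data.files
                     if key.startswith(prefix + ".")}
            net.load_state_dict(state)
    return model
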