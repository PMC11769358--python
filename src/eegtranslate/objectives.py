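"""Training objectives for the translation model.

The generator is trained with a composite loss

    L_G = L_Gh + lambda1 * L_KL + lambda2 * L_L1 + lambda3 * L_FM,

where L_Gh is the hinge adversarial term, L_KL the Kullback-Leibler
divergence of the encoder posterior from the standard-normal prior, L_L1 the
reconstruction distance between real and estimated intracranial segments,
and L_FM the feature-matching distance over the discriminator's intermediate
activations.  The discriminator is trained with the two-sided hinge loss.

Every function accepts either plain numpy arrays (returning a float) or
autodiff :class:`~eegtranslate._autograd.Tensor` inputs (returning a Tensor),
so the same code path is used for unit testing and for training.

Expectations are realized as means over the batch axis; for batched inputs
axis 0 is the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, astensor

__all__ = [
    "LossWeights",
    "kl_loss",
    "hinge_d_loss",
    "hinge_g_loss",
    "l1_loss",
    "feature_matching_loss",
    "generator_total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    """Penalty weights (lambda1, lambda2, lambda3) of the generator loss.

    Defaults follow the conventions of conditional image-translation GANs
    (small KL weight, strong reconstruction weight), adjusted for this
    package's feature-matching normalization: the per-layer distance sums
    over all map elements before the 1/F_i scaling, so its raw magnitude is
    roughly the map size times the mean element error, and a unit weight
    already gives it gradient influence comparable to the L1 term.
    """

    lambda_kl: float = 0.05
    lambda_l1: float = 100.0
    lambda_fm: float = 1.0

    def __post_init__(self):
        if min(self.lambda_kl, self.lambda_l1, self.lambda_fm) < 0:
            raise ValueError("loss weights must be nonnegative")


def _maybe_item(result: Tensor, *inputs) -> Tensor | float:
    if any(isinstance(x, Tensor) for x in inputs):
        return result
    return result.item()


def kl_loss(mu, sigma):
    """KL divergence of N(mu, diag(sigma^2)) from N(0, I).

    Computed as -1/2 * sum_z (1 + log sigma_z^2 - mu_z^2 - sigma_z^2); for
    batched (B, Z) inputs the per-sample sums are averaged over the batch.
    Nonnegative, zero exactly at mu=0, sigma=1.
    """
    mu_t, sigma_t = astensor(mu), astensor(sigma)
    if mu_t.shape != sigma_t.shape:
        raise ValueError(f"mu shape {mu_t.shape} != sigma shape {sigma_t.shape}")
    if np.any(sigma_t.data <= 0):
        raise ValueError("sigma must be strictly positive")
    var = sigma_t * sigma_t
    per = -0.5 * (1.0 + var.log() - mu_t * mu_t - var).sum(axis=-1)
    out = per.mean() if per.data.ndim else per
    return _maybe_item(out, mu, sigma)


def hinge_d_loss(scores_real, scores_fake):
    """Two-sided hinge loss for the discriminator.

    mean(max(0, 1 - s_real)) + mean(max(0, 1 + s_fake)); zero exactly when
    every real score is >= 1 and every fake score is <= -1.
    """
    r, f = astensor(scores_real), astensor(scores_fake)
    loss = (1.0 - r).clip_min(0.0).mean() + (1.0 + f).clip_min(0.0).mean()
    return _maybe_item(loss, scores_real, scores_fake)


def hinge_g_loss(scores_fake):
    """Adversarial generator term: negative mean of fake patch scores."""
    f = astensor(scores_fake)
    return _maybe_item(-f.mean(), scores_fake)


def l1_loss(y, y_est):
    """Mean absolute difference between real and estimated segments."""
    yt, et = astensor(y), astensor(y_est)
    if yt.shape != et.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {et.shape}")
    return _maybe_item((yt - et).abs().mean(), y, y_est)


def feature_matching_loss(features_real, features_fake):
    """Feature-matching distance over discriminator layers.

    sum_i (1/F_i) * ||feat_real_i - feat_fake_i||_1, where F_i is the number
    of feature channels of layer i and ||.||_1 sums absolute differences over
    all per-sample elements of the map; batched maps (batch on axis 0,
    channels on axis 1) are averaged over the batch.
    """
    if len(features_real) != len(features_fake):
        raise ValueError(
            f"feature list lengths differ: {len(features_real)} vs {len(features_fake)}"
        )
    total = None
    for i, (fr, ff) in enumerate(zip(features_real, features_fake)):
        frt, fft = astensor(fr), astensor(ff)
        if frt.shape != fft.shape:
            raise ValueError(f"layer {i}: shape {frt.shape} vs {fft.shape}")
        diff = (frt - fft).abs()
        if diff.data.ndim <= 1:  # single feature vector, F = length
            term = diff.sum() * (1.0 / diff.shape[-1])
        else:
            n_features = diff.shape[1]
            per_sample = diff.reshape(diff.shape[0], -1).sum(axis=1)
            term = per_sample.mean() * (1.0 / n_features)
        total = term if total is None else total + term
    return _maybe_item(total, *features_real, *features_fake)


def generator_total_loss(h, kl, l1, fm, w: LossWeights):
    """Composite generator loss: h + lambda1*kl + lambda2*l1 + lambda3*fm."""
    total = astensor(h) + w.lambda_kl * astensor(kl) \
        + w.lambda_l1 * astensor(l1) + w.lambda_fm * astensor(fm)
    return _maybe_item(total, h, kl, l1, fm)
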