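"""Independent brute-force oracles used across the test suite.

These deliberately use explicit Python loops / quadrature and share no code
with the package implementation.
"""

import numpy as np
from scipy.integrate import quad


def kl_gaussian_quadrature(mu, sigma):
    """KL(N(mu_z, sigma_z^2) || N(0,1)) summed over dimensions, by numerical
    integration of p*log(p/q)."""
    total = 0.0
    for m, s in zip(np.ravel(mu), np.ravel(sigma)):
        def integrand(x, m=m, s=s):
            p = np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            q = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
            return p * (np.log(p) - np.log(q)) if p > 0 else 0.0
        lo, hi = m - 12 * s, m + 12 * s
        total += quad(integrand, lo, hi, limit=200)[0]
    return total


def hinge_d_loop(real, fake):
    real, fake = np.asarray(real, float), np.asarray(fake, float)
    acc_r = sum(max(0.0, 1.0 - v) for v in real.ravel()) / real.size
    acc_f = sum(max(0.0, 1.0 + v) for v in fake.ravel()) / fake.size
    return acc_r + acc_f


def l1_loop(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return sum(abs(x - y) for x, y in zip(a.ravel(), b.ravel())) / a.size


def fm_loop(feats_real, feats_fake):
    total = 0.0
    for fr, ff in zip(feats_real, feats_fake):
        fr, ff = np.asarray(fr, float), np.asarray(ff, float)
        if fr.ndim <= 1:
            total += sum(abs(x - y) for x, y in zip(fr.ravel(), ff.ravel())) / fr.shape[-1]
        else:
            batch_terms = []
            for b in range(fr.shape[0]):
                s = sum(abs(x - y) for x, y in zip(fr[b].ravel(), ff[b].ravel()))
                batch_terms.append(s / fr.shape[1])
            total += float(np.mean(batch_terms))
    return total


def mse_loop(y, y_est):
    return sum((a - b) ** 2 for a, b in zip(y, y_est)) / len(y)


def cossim_loop(y, y_est):
    num = sum(a * b for a, b in zip(y, y_est))
    ny = sum(a * a for a in y) ** 0.5
    ne = sum(b * b for b in y_est) ** 0.5
    return num / (ny * ne)


def pcorr_loop(y, y_est):
    n = len(y)
    my, me = sum(y) / n, sum(y_est) / n
    cov = sum((a - my) * (b - me) for a, b in zip(y, y_est)) / n
    sy = (sum((a - my) ** 2 for a in y) / n) ** 0.5
    se = (sum((b - me) ** 2 for b in y_est) / n) ** 0.5
    return cov / (sy * se)


def spade_modulate_loop(gamma, beta, a):
    gamma, beta, a = (np.asarray(x, float) for x in (gamma, beta, a))
    out = np.zeros_like(a)
    it = np.nditer(a, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = gamma[idx] * a[idx] + beta[idx]
    return out
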