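"""Exact fractional Gaussian noise via Davies-Harte circulant embedding.

Fractional Brownian motion (fBm) is the standard phenomenological model for
subdiffusive chromatin-locus motion: a zero-mean Gaussian process whose MSD
grows as t^alpha with correlated increments (Hurst index H = alpha / 2).
The increments form fractional Gaussian noise (fGn) with autocovariance

    gamma(k) = 0.5 * (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H))

for unit one-step variance. The Davies-Harte construction embeds the n x n
Toeplitz covariance into a 2n circulant matrix, diagonalized by the FFT, and
is exact whenever all circulant eigenvalues are non-negative (true for
0 < H < 1 and all n of practical interest). A Cholesky fallback covers the
rare failure and very short tracks.
"""

from __future__ import annotations

import numpy as np


def fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(0..n-1) of standard fGn with Hurst index ``hurst``."""
    k = np.arange(n, dtype=np.float64)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)


def sample_fgn(n: int, hurst: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw ``size`` independent standard-fGn sequences of length ``n``.

    Returns an array of shape ``(size, n)`` with unit one-step variance and
    exact covariance (partial sums have variance k^(2H)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < hurst <= 1.0:
        raise ValueError("hurst must be in (0, 1]")
    if hurst == 1.0:
        # perfectly correlated (ballistic) limit: one shared normal per track
        z = rng.standard_normal((size, 1))
        return np.repeat(z, n, axis=1)
    if hurst == 0.5:
        return rng.standard_normal((size, n))
    gamma = fgn_autocovariance(n, hurst)
    m = 2 * n
    row = np.empty(m)
    row[: n] = gamma
    row[n] = 0.0
    row[n + 1:] = gamma[1:][::-1]
    lam = np.fft.fft(row).real
    if np.min(lam) < -1e-9 * np.max(lam):
        return _fgn_cholesky(gamma, rng, size)
    lam = np.clip(lam, 0.0, None)

    # Hermitian-symmetric complex spectrum -> real FFT output
    w = np.zeros((size, m), dtype=np.complex128)
    w[:, 0] = np.sqrt(lam[0] / m) * rng.standard_normal(size)
    w[:, n] = np.sqrt(lam[n] / m) * rng.standard_normal(size)
    v1 = rng.standard_normal((size, n - 1))
    v2 = rng.standard_normal((size, n - 1))
    scale = np.sqrt(lam[1:n] / (2.0 * m))
    w[:, 1:n] = scale * (v1 + 1j * v2)
    w[:, n + 1:] = np.conj(w[:, 1:n][:, ::-1])
    out = np.fft.fft(w, axis=1).real[:, :n]
    return out


def _fgn_cholesky(gamma: np.ndarray, rng: np.random.Generator, size: int) -> np.ndarray:
    n = len(gamma)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov = gamma[idx]
    # tiny jitter guards against numerically semidefinite matrices
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return rng.standard_normal((size, n)) @ chol.T


def fbm_increments(
    n_steps: int,
    alpha: float,
    coefficient: float,
    dt: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Per-axis fBm increments for a 2-D process with MSD(t) = coefficient * t^alpha.

    ``coefficient`` is the full 2-D anomalous coefficient A (μm²/s^alpha);
    each axis contributes A/2 * t^alpha, so a one-step increment has
    per-axis variance (A/2) * dt^alpha.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must be in (0, 2]")
    if coefficient < 0:
        raise ValueError("coefficient must be >= 0")
    if coefficient == 0.0:
        return np.zeros((size, n_steps))
    sigma = np.sqrt(0.5 * coefficient * dt ** alpha)
    return sigma * sample_fgn(n_steps, alpha / 2.0, rng, size=size)
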