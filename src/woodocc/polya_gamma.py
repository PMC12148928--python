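"""Vectorized sampler for the Polya-Gamma distribution PG(1, c).

A PG(1, c) variate is an infinite convolution of scaled exponentials,

    omega = 1/(2 pi^2) * sum_{k>=1} g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)),

with g_k iid Exp(1). Augmenting each Bernoulli-logit observation with such an
omega makes every regression layer of the occupancy model conditionally
Gaussian, which is what the Gibbs sampler exploits.

The series is truncated at ``_N_TERMS`` draws and the omitted tail is replaced
by its conditional mean (the tail's variance decays like K^-3, so the
replacement error is ~1e-9 at K=64). Closed-form moments used by the tests:

    E[omega]   = tanh(c/2) / (2 c)                       (1/4 at c = 0)
    Var[omega] = sech^2(c/2) * (sinh(c) - c) / (4 c^3)   (1/24 at c = 0)
"""

from __future__ import annotations

import numpy as np

_N_TERMS = 64
# (k - 1/2)^2 for the retained series terms
_KSQ = (np.arange(1, _N_TERMS + 1) - 0.5) ** 2


_CHUNK = 1 << 18  # bound the (n, _N_TERMS) scratch array to ~128 MiB


def _sample_pg_flat(rng: np.random.Generator, h: np.ndarray) -> np.ndarray:
    n = h.size
    g = rng.standard_exponential(size=(n, _N_TERMS))
    omega = (g / (_KSQ[None, :] + h[:, None])).sum(axis=1)
    # tail mean: sum_{k>K} 1/((k-1/2)^2 + h) ~ integral_{K}^{inf} dx/((x-1/2)^2+h)
    edge = _N_TERMS + 0.5  # continuity-corrected lower limit
    sqrt_h = np.sqrt(np.maximum(h, 1e-300))
    tail = np.where(
        h > 1e-12,
        (np.pi / 2 - np.arctan(edge / sqrt_h)) / sqrt_h,
        1.0 / edge,
    )
    return (omega + tail) / (2.0 * np.pi**2)


def sample_pg(rng: np.random.Generator, c: np.ndarray) -> np.ndarray:
    """Draw one PG(1, c[i]) variate per element of ``c`` (any shape)."""
    c = np.asarray(c, dtype=float)
    shape = c.shape
    h = (c.ravel() ** 2) / (4.0 * np.pi**2)  # (n,)
    out = np.empty(h.size)
    for start in range(0, h.size, _CHUNK):
        out[start : start + _CHUNK] = _sample_pg_flat(rng, h[start : start + _CHUNK])
    return out.reshape(shape)


def pg_mean(c: np.ndarray) -> np.ndarray:
    """E[PG(1, c)], with the c -> 0 limit 1/4 handled."""
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, 0.25)
    nz = np.abs(c) > 1e-8
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out


def pg_var(c: np.ndarray) -> np.ndarray:
    """Var[PG(1, c)], with the c -> 0 limit 1/24 handled."""
    c = np.asarray(c, dtype=float)
    out = np.full_like(c, 1.0 / 24.0)
    nz = np.abs(c) > 1e-6
    cz = c[nz]
    out[nz] = (np.sinh(cz) - cz) / (4.0 * cz**3 * np.cosh(cz / 2.0) ** 2)
    return out
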