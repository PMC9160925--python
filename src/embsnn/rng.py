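"""Counter-based random streams for worker-invariant simulation.

Every stochastic decision in the kernel (connectivity sampling, Poisson
drive, bias currents, initial membrane potentials, neuron placement) is a
pure function of ``(master_seed, purpose, *indices)``.  Because draws are
keyed by the *global* identity of the entity that consumes them -- never by
which logical worker happens to own it or by iteration order -- the spike
output of a network is bitwise identical for any worker count.

The generator is a splitmix64-style avalanche hash evaluated with vectorized
uint64 arithmetic.  numpy's counter-based bit generators (Philox) cannot draw
with a distinct key per array element in one call, which is exactly the
access pattern needed here, so the mixing function is implemented directly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "PURPOSE",
    "uniform",
    "normal",
    "poisson",
    "randint",
]

# Registry of stream purposes.  Values only need to be distinct.
PURPOSE = {
    "connect": 1,
    "poisson_drive": 2,
    "bias_current": 3,
    "v_init": 4,
    "positions": 5,
    "calibrate": 6,
}

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_TO53 = 1.0 / 9007199254740992.0  # 2**-53


def _mix(z: np.ndarray) -> np.ndarray:
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    return z ^ (z >> _S31)


def _hash(seed: int, purpose: int, *indices) -> np.ndarray:
    """Avalanche-hash the key tuple to uint64 words.

    Scalar and array indices broadcast against each other; the result has
    the broadcast shape.  uint64 arithmetic wraps modulo 2**64 by design.
    """
    with np.errstate(over="ignore"):
        h = _mix(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) * _GOLDEN + np.uint64(purpose))
        for ix in indices:
            ix = np.asarray(ix, dtype=np.uint64)
            h = _mix((h + np.uint64(1)) * _GOLDEN ^ (ix * _MIX1 + _GOLDEN))
        if np.ndim(h) == 0:
            h = _mix(h + _GOLDEN)
    return h


def uniform(seed: int, purpose: int, *indices) -> np.ndarray:
    """U[0, 1) draws, one per element of the broadcast index tuple."""
    h = _hash(seed, purpose, *indices)
    return np.asarray((h >> _S11).astype(np.float64) * _TO53)


def normal(seed: int, purpose: int, *indices) -> np.ndarray:
    """Standard-normal draws via Box-Muller on two decorrelated sub-streams."""
    u1 = uniform(seed, purpose, *indices, 0)
    u2 = uniform(seed, purpose, *indices, 1)
    # guard log(0)
    u1 = np.maximum(u1, _TO53)
    return np.asarray(np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2))


def randint(seed: int, purpose: int, n: int, *indices) -> np.ndarray:
    """Integer draws in [0, n) keyed by the index tuple."""
    return np.minimum((uniform(seed, purpose, *indices) * n).astype(np.int64), n - 1)


def poisson(lam, seed: int, purpose: int, *indices) -> np.ndarray:
    """Poisson counts by CDF inversion; intended for the small means that
    arise from per-step spike generation (lam up to a few)."""
    u = uniform(seed, purpose, *indices)
    lam = np.broadcast_to(np.asarray(lam, dtype=np.float64), u.shape).copy()
    k = np.zeros(u.shape, dtype=np.int64)
    p = np.exp(-lam)
    cdf = p.copy()
    active = u >= cdf
    # bound: mean + 12 sd covers any plausible tail at these rates
    kmax = int(np.ceil(lam.max() + 12.0 * np.sqrt(lam.max() + 1.0))) + 1
    i = 0
    while active.any() and i < kmax:
        i += 1
        p = p * lam / i
        cdf = cdf + p
        k[active] += 1
        active = u >= cdf
    return k
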