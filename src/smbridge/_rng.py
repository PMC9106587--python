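"""Low-level counter-free RNG primitives for the numba photon kernel.

xoshiro256** with splitmix64 seeding, a polar-method Gaussian and an
inversion-sampling Poisson.  numba's builtin distributions are several times
slower per draw, which matters when a 60-s acquisition needs ~1e9 Gaussian
steps; the generators here are deterministic functions of the 4-word state
they mutate, so simulations are exactly reproducible from an integer seed.
"""

import numpy as np
from numba import njit

__all__ = ["seed_state", "next_u64", "rand_u01", "rand_gauss", "rand_poisson"]

_U64 = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


def seed_state(seed: int) -> np.ndarray:
    """Expand an integer seed into a 4-word xoshiro256** state via splitmix64."""
    mask = (1 << 64) - 1
    state = np.empty(4, dtype=np.uint64)
    x = int(seed) & mask
    for i in range(4):
        x = (x + 0x9E3779B97F4A7C15) & mask
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        state[i] = _U64(z ^ (z >> 31))
    if not state.any():  # all-zero state is the one forbidden xoshiro state
        state[0] = _U64(0x9E3779B97F4A7C15)
    return state


@njit(inline="always", cache=True, fastmath=True)
def next_u64(s):
    t = s[1] * _U64(5)
    r = ((t << _U64(7)) | (t >> _U64(57))) * _U64(9)
    t = s[1] << _U64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = (s[3] << _U64(45)) | (s[3] >> _U64(19))
    return r


@njit(inline="always", cache=True, fastmath=True)
def rand_u01(s):
    """Uniform double in [0, 1) with 53 random bits."""
    return (next_u64(s) >> _U64(11)) * _INV53


@njit(inline="always", cache=True, fastmath=True)
def rand_gauss(s, cache):
    """Standard normal; Marsaglia polar method with one cached spare.

    ``cache`` is a 2-element float64 scratch: cache[0] is a has-spare flag,
    cache[1] the spare value.
    """
    if cache[0] != 0.0:
        cache[0] = 0.0
        return cache[1]
    while True:
        u = 2.0 * rand_u01(s) - 1.0
        v = 2.0 * rand_u01(s) - 1.0
        r2 = u * u + v * v
        if 0.0 < r2 < 1.0:
            f = np.sqrt(-2.0 * np.log(r2) / r2)
            cache[0] = 1.0
            cache[1] = v * f
            return u * f


@njit(inline="always", cache=True, fastmath=True)
def rand_poisson(s, lam):
    """Poisson variate by inversion; adequate for the small per-step means here."""
    total = 0
    remaining = lam
    # split large means into <=25 chunks so the inversion loop stays bounded
    while remaining > 25.0:
        limit = np.exp(-25.0)
        p = 1.0
        k = -1
        while p > limit:
            k += 1
            p *= rand_u01(s)
        total += k
        remaining -= 25.0
    if remaining > 0.0:
        limit = np.exp(-remaining)
        p = 1.0
        k = -1
        while p > limit:
            k += 1
            p *= rand_u01(s)
        total += k
    return total
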