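"""Counter-based pseudo-random streams with one independent substream per photon.

The engine needs two properties that ``numpy.random`` streams do not give
cheaply inside a compiled kernel:

* *reproducibility per photon* — photon ``i`` consumes exactly the same
  deviates regardless of how many photons run before it, so results are
  invariant to execution order and a single photon can be replayed;
* *bit-exact portability between the compiled kernel and the pure-Python
  reference engine* — both sides perform identical 64-bit integer
  arithmetic, so their floating-point deviates are identical.

The generator is the splitmix64 finalizer applied to a Weyl sequence
(additive constant 0x9E3779B97F4A7C15).  Each photon's starting state is a
mix of the run seed and the photon index.  Statistical quality is more than
adequate for transport sampling (the finalizer passes BigCrush as the
output function of splitmix64).

Uniform deviates are produced on the half-open interval [0, 1) from the top
53 bits; ``next_open01`` returns 1 - u in (0, 1] for use under ``log``.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

MASK64 = 0xFFFFFFFFFFFFFFFF
_WEYL = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB

_U64_WEYL = np.uint64(_WEYL)
_U64_MIX1 = np.uint64(_MIX1)
_U64_MIX2 = np.uint64(_MIX2)
_U64_30 = np.uint64(30)
_U64_27 = np.uint64(27)
_U64_31 = np.uint64(31)
_U64_11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


def mix64_py(x: int) -> int:
    """splitmix64 finalizer on a 64-bit integer (pure Python)."""
    x &= MASK64
    x = ((x ^ (x >> 30)) * _MIX1) & MASK64
    x = ((x ^ (x >> 27)) * _MIX2) & MASK64
    return x ^ (x >> 31)


def photon_state_py(seed: int, index: int) -> int:
    """Initial stream state for photon ``index`` under run ``seed``."""
    x = (seed * _WEYL + (index + 1) * _MIX1) & MASK64
    return mix64_py(x)


def next_state_py(state: int) -> int:
    return (state + _WEYL) & MASK64


def state_to_unit_py(state: int) -> float:
    """Uniform deviate in [0, 1) from a stream state."""
    return (mix64_py(state) >> 11) * _INV53


class PhotonRNG:
    """Per-photon deviate stream (pure-Python side).

    Used by the reference engine and by the public sampling wrappers; the
    compiled kernel reproduces the identical sequence with uint64 arithmetic.
    """

    __slots__ = ("state",)

    def __init__(self, seed: int, photon_index: int = 0):
        self.state = photon_state_py(seed, photon_index)

    def next_float(self) -> float:
        """Uniform in [0, 1)."""
        self.state = next_state_py(self.state)
        return state_to_unit_py(self.state)

    def next_open01(self) -> float:
        """Uniform in (0, 1]; safe under log."""
        return 1.0 - self.next_float()


@njit(cache=False)
def mix64(x):
    x = uint64(x)
    x = (x ^ (x >> _U64_30)) * _U64_MIX1
    x = (x ^ (x >> _U64_27)) * _U64_MIX2
    return x ^ (x >> _U64_31)


@njit(cache=False)
def photon_state(seed, index):
    x = uint64(seed) * _U64_WEYL + (uint64(index) + uint64(1)) * _U64_MIX1
    return mix64(x)


@njit(cache=False)
def next_state(state):
    return uint64(state) + _U64_WEYL


@njit(cache=False)
def state_to_unit(state):
    return float(mix64(state) >> _U64_11) * _INV53


def stream_floats(seed: int, photon_index: int, n: int) -> np.ndarray:
    """First ``n`` uniform [0,1) deviates of a photon stream (vectorised)."""
    states = (photon_state_py(seed, photon_index) + _WEYL * np.arange(1, n + 1, dtype=np.uint64)) & np.uint64(MASK64)
    x = states.copy()
    x ^= x >> np.uint64(30)
    x *= np.uint64(_MIX1)
    x ^= x >> np.uint64(27)
    x *= np.uint64(_MIX2)
    x ^= x >> np.uint64(31)
    return (x >> np.uint64(11)).astype(np.float64) * _INV53
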