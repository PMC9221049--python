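"""Counter-based pseudo-random number streams.

Every stochastic site in a simulation (one calcium release unit, one
protocol-level choice, ...) owns an independent stream identified by
``(seed, cell, cru, purpose)``.  A draw is a pure function of the stream
identity and a per-stream counter, so the sequence a site sees never
depends on the order in which other sites are updated.  This is what makes
network simulations bit-reproducible under any update schedule, and it is
cheap enough to call from compiled kernels.

The generator is a splitmix64-style avalanche mixer applied to the packed
(seed, identity, counter) words.  53-bit mantissa uniforms are produced
from the high bits.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64, float64

__all__ = ["mix64", "counter_uniform", "stream_ident", "RNGStream", "derive_stream"]

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MULT_A = np.uint64(0xBF58476D1CE4E5B9)
_MULT_B = np.uint64(0x94D049BB133111EB)
_IDENT_CELL = np.uint64(0xD1342543DE82EF95)
_IDENT_CRU = np.uint64(0xA24BAED4963EE407)
_IDENT_PURPOSE = np.uint64(0x9FB21C651E98DF25)
_INV_2_53 = float64(1.0 / 9007199254740992.0)


@njit(uint64(uint64), cache=True, inline="always")
def mix64(x):
    """Finalizing avalanche mixer (splitmix64)."""
    x = (x + _GOLDEN) & uint64(0xFFFFFFFFFFFFFFFF)
    z = x
    z = (z ^ (z >> uint64(30))) * _MULT_A
    z = (z ^ (z >> uint64(27))) * _MULT_B
    z = z ^ (z >> uint64(31))
    return z


@njit(uint64(uint64, uint64, uint64), cache=True, inline="always")
def stream_ident(cell, cru, purpose):
    """Pack a stream identity into one 64-bit word (injective up to mixing)."""
    return cell * _IDENT_CELL + cru * _IDENT_CRU + purpose * _IDENT_PURPOSE


@njit(float64(uint64, uint64, uint64), cache=True, inline="always")
def counter_uniform(seed, ident, counter):
    """Uniform draw on [0, 1) for stream (seed, ident) at position `counter`."""
    z = mix64(mix64(seed ^ ident) + counter * _GOLDEN)
    return float64(z >> uint64(11)) * _INV_2_53


class RNGStream:
    """A positioned, independent uniform stream.

    Streams with distinct ``(cell, cru, purpose)`` identities under the same
    seed are statistically independent; identical identity and seed reproduce
    the identical sequence regardless of what other streams have consumed.
    """

    __slots__ = ("seed", "cell", "cru", "purpose", "counter", "_ident")

    def __init__(self, seed: int, cell: int = 0, cru: int = 0, purpose: int = 0,
                 counter: int = 0):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        self.cell = int(cell)
        self.cru = int(cru)
        self.purpose = int(purpose)
        self.counter = int(counter)
        self._ident = int(stream_ident(np.uint64(cell), np.uint64(cru),
                                       np.uint64(purpose)))

    def uniform(self, size: int | None = None):
        """Draw uniforms on [0,1), advancing the stream position."""
        if size is None:
            u = counter_uniform(np.uint64(self.seed), np.uint64(self._ident),
                                np.uint64(self.counter))
            self.counter += 1
            return float(u)
        out = np.empty(size, dtype=np.float64)
        s, ident = np.uint64(self.seed), np.uint64(self._ident)
        for i in range(size):
            out[i] = counter_uniform(s, ident, np.uint64(self.counter + i))
        self.counter += size
        return out

    def integers(self, high: int, size: int | None = None):
        """Draw integers uniform on [0, high)."""
        if size is None:
            return int(self.uniform() * high)
        return np.minimum((self.uniform(size) * high).astype(np.int64), high - 1)

    def choice_without_replacement(self, n: int, k: int) -> np.ndarray:
        """Deterministic sample of k distinct indices from range(n).

        Partial Fisher-Yates driven by this stream; the subset size is exact.
        """
        if not 0 <= k <= n:
            raise ValueError(f"cannot choose {k} from {n}")
        idx = np.arange(n, dtype=np.int64)
        for i in range(k):
            j = i + self.integers(n - i)
            idx[i], idx[j] = idx[j], idx[i]
        out = idx[:k].copy()
        out.sort()
        return out

    def spawn(self, cell: int | None = None, cru: int | None = None,
              purpose: int | None = None) -> "RNGStream":
        """Derive a fresh stream with a modified identity, position 0."""
        return RNGStream(
            self.seed,
            self.cell if cell is None else cell,
            self.cru if cru is None else cru,
            self.purpose if purpose is None else purpose,
        )

    def __repr__(self):  # pragma: no cover
        return (f"RNGStream(seed={self.seed}, cell={self.cell}, cru={self.cru}, "
                f"purpose={self.purpose}, counter={self.counter})")


def derive_stream(seed: int, cell: int = 0, cru: int = 0, purpose: int = 0) -> RNGStream:
    """Derive the independent uniform stream for one stochastic site."""
    return RNGStream(seed, cell, cru, purpose)
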