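"""Buffered random-number helper.

The Monte Carlo loop draws very large numbers of scalar uniforms (one per
collision pairing, per Bernoulli event on a strand, ...).  Calling
``Generator.random()`` once per draw dominates the runtime, so scalar draws
are served from a pre-filled block.  Vector draws (binomial/multinomial over
room arrays) go straight to the underlying :class:`numpy.random.Generator`.

Determinism contract: all draws come from one PCG64 stream, consumed in a
fixed order, so identical (config, seed) gives identical trajectories.
"""

from __future__ import annotations

import numpy as np

_BLOCK = 8192


class BufferedRNG:
    """One PCG64 stream with a buffered scalar-uniform front end."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.gen = np.random.Generator(np.random.PCG64(self.seed))
        self._buf = self.gen.random(_BLOCK)
        self._pos = 0

    def uniform(self) -> float:
        """One U(0,1) scalar."""
        if self._pos >= _BLOCK:
            self._buf = self.gen.random(_BLOCK)
            self._pos = 0
        u = self._buf[self._pos]
        self._pos += 1
        return u

    def bernoulli(self, p: float) -> bool:
        if p <= 0.0:
            return False
        if p >= 1.0:
            return True
        return self.uniform() < p

    def randbelow(self, n: int) -> int:
        """Uniform integer in [0, n)."""
        return int(self.uniform() * n)

    def choice(self, seq):
        return seq[self.randbelow(len(seq))]

    def shuffle(self, seq: list) -> None:
        # Fisher-Yates on a Python list using the buffered stream.
        for i in range(len(seq) - 1, 0, -1):
            j = self.randbelow(i + 1)
            seq[i], seq[j] = seq[j], seq[i]

    # vector draws pass through
    def binomial(self, n, p):
        return self.gen.binomial(n, p)

    def multinomial(self, n, pvals):
        return self.gen.multinomial(n, pvals)

    def spawn_seed(self) -> int:
        """Derive a fresh sub-seed (for independent runs in sweeps)."""
        return int(self.gen.integers(0, 2**31 - 1))
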