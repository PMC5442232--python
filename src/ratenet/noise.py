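"""Counter-based, replayable noise streams.

Every unit consumes exactly one standard-normal draw per time step.  The
draw for (seed, unit, step) is a pure function of those three integers: the
simulation grid is tiled into fixed blocks of ``BLOCK`` steps and the block
``b`` of a run keyed by ``seed`` is generated in one shot from
``Philox(SeedSequence([seed, b]))`` as a (BLOCK, N) matrix whose column
``u`` belongs to unit ``u``.

Consequences that the schedulers rely on:

* trajectories are bitwise independent of how the run is chunked into
  communication intervals,
* waveform-relaxation sweeps replay the identical noise on every iteration,
* an approximate scheme and the exact linear propagator can be driven by
  the same increments, which makes their RMSE well defined.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NoiseSource", "BLOCK"]

BLOCK = 256


class NoiseSource:
    """Standard-normal increments eta[k, u] for steps k and units 0..N-1."""

    def __init__(self, seed: int, n_units: int, cache_blocks: int = 8):
        self.seed = int(seed)
        self.n_units = int(n_units)
        self._cache: dict[int, np.ndarray] = {}
        self._cache_blocks = cache_blocks

    def _block(self, b: int) -> np.ndarray:
        arr = self._cache.get(b)
        if arr is None:
            bg = np.random.Philox(np.random.SeedSequence([self.seed, b]))
            arr = np.random.Generator(bg).standard_normal((BLOCK, self.n_units))
            if len(self._cache) >= self._cache_blocks:
                self._cache.pop(next(iter(self._cache)))
            self._cache[b] = arr
        return arr

    def normals(self, k0: int, n_steps: int) -> np.ndarray:
        """Return eta for steps k0 .. k0+n_steps-1, shape (n_steps, N)."""
        if n_steps <= 0:
            return np.empty((0, self.n_units))
        parts = []
        k = k0
        end = k0 + n_steps
        while k < end:
            b, off = divmod(k, BLOCK)
            take = min(BLOCK - off, end - k)
            parts.append(self._block(b)[off : off + take])
            k += take
        return parts[0].copy() if len(parts) == 1 else np.concatenate(parts, axis=0)
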