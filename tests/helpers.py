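"""Shared test utilities."""

import numpy as np


def batch_se(values, n_blocks=1000):
    """Standard error of the mean via batch means.

    Successive centroid jumps are correlated, so the naive iid standard
    error understates the Monte Carlo uncertainty; averaging consecutive
    blocks first gives nearly independent block means.
    """
    x = np.asarray(values, dtype=float)
    m = len(x) // n_blocks
    if m < 2:
        raise ValueError("too few values for the requested number of blocks")
    blocks = x[: m * n_blocks].reshape(n_blocks, m).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


class StubRNG:
    """Replays a preset list of uniforms; lets tests force specific events."""

    def __init__(self, values):
        self._values = list(values)

    def random(self):
        return self._values.pop(0)
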