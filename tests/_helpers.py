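"""Shared construction helpers for the test suite."""

import numpy as np

from deltarad.preprocessing import QuantizedROI


def make_quantized(levels, ng=None, spacing=(1.0, 1.0, 1.0)) -> QuantizedROI:
    """QuantizedROI from a 3D int array; 0 marks outside-ROI voxels."""
    levels = np.asarray(levels, dtype=np.int64)
    mask = levels > 0
    if ng is None:
        ng = int(levels.max())
    return QuantizedROI(levels=levels, mask=mask, ng=ng, spacing=spacing)


def random_quantized(rng, max_shape=(8, 8, 4), ng=8, p_mask=0.7) -> QuantizedROI:
    """Random small ROI: irregular mask, uniform levels in 1..ng."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[tuple(0 for _ in shape)] = True
    levels = np.where(mask, rng.integers(1, ng + 1, size=shape), 0)
    return make_quantized(levels, ng=ng)
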