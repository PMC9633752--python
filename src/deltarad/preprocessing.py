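"""ROI intensity normalization and gray-level quantization.

Texture matrices are computed on small integer gray levels, not raw MR
intensities.  The pipeline fixes the order of the two preparation steps:

1. **Dynamic-range constraint** (Collewet ±kσ): ROI intensities are clipped
   into ``[mean - k*sd, mean + k*sd]`` with the statistics taken over the
   ROI voxels only, so background never influences the dynamic range.
   ``k = 3`` by default.
2. **Histogram equalization to Ng levels** (``Ng = 64`` by default): each
   voxel receives level ``floor(Ng * F⁻(x)) + 1`` where ``F⁻(x)`` is the
   fraction of ROI voxels strictly below ``x`` (the left limit of the
   empirical CDF).  Tied intensities share a level, the mapping is
   monotone, re-quantizing the levels is a no-op (idempotent), and for
   many i.i.d. continuous draws every level ends up equally occupied.

A zero-variance ROI (all voxels equal) is the degenerate case ``F⁻ = 0``:
every voxel is assigned level 1, so downstream single-level texture
matrices are still well formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageVolume, ROIMask

__all__ = ["QuantizedROI", "collewet_normalize", "quantize_equalize", "quantize_roi"]


@dataclass(frozen=True)
class QuantizedROI:
    """ROI voxels mapped to integer gray levels ``1..ng``.

    ``levels`` is a dense 3D int array over the mask bounding box with 0
    outside the ROI; ``mask`` marks ROI membership on the same grid.
    """

    levels: np.ndarray          # 3D int array, 0 outside ROI, 1..ng inside
    mask: np.ndarray            # 3D bool array, same shape
    ng: int
    spacing: tuple[float, float, float]

    def __post_init__(self):
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("quantized ROI has no voxels")
        if inside.min() < 1 or inside.max() > self.ng:
            raise ValueError("levels outside 1..ng")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def roi_levels(self) -> np.ndarray:
        """Flat array of the levels of the ROI voxels."""
        return self.levels[self.mask]


def collewet_normalize(
    values, k_sigma: float = 3.0, sigma_divisor: str = "n"
) -> np.ndarray:
    """Clip ROI intensities into ``mean ± k_sigma * sd``.

    Parameters
    ----------
    values
        ROI intensities (any shape; flattened view is used for statistics).
    k_sigma
        Half-width of the retained dynamic range in standard deviations.
    sigma_divisor
        ``"n"`` for the population standard deviation (default) or
        ``"n-1"`` for the sample estimator.  The choice only moves the clip
        boundary slightly; it is exposed so the convention is explicit.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite ROI intensities")
    if sigma_divisor not in ("n", "n-1"):
        raise ValueError(f"sigma_divisor must be 'n' or 'n-1', got {sigma_divisor!r}")
    ddof = 0 if sigma_divisor == "n" else 1
    if values.size == 1 and ddof == 1:
        sd = 0.0
    else:
        sd = float(values.std(ddof=ddof))
    mu = float(values.mean())
    lo, hi = mu - k_sigma * sd, mu + k_sigma * sd
    return np.clip(values, lo, hi)


def quantize_equalize(values, ng: int = 64) -> np.ndarray:
    """Histogram-equalize intensities to integer levels ``1..ng``.

    level(x) = floor(ng * F⁻(x)) + 1 with F⁻ the left-limit empirical CDF
    (fraction of inputs strictly below x), so a constant input maps to
    level 1 and quantizing already-quantized levels changes nothing.
    Returns an int array of the same shape as ``values``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite ROI intensities")
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")

    flat = values.ravel()
    uniq, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    cdf_below = (np.cumsum(counts) - counts) / flat.size   # P(X < x)
    # the 1e-9 guard keeps floor() from undershooting when ng*cdf is an
    # exact integer up to float rounding (distinct attainable products
    # differ by >= ng/n, orders of magnitude larger than the guard)
    level_of_uniq = np.floor(ng * cdf_below + 1e-9).astype(np.int64) + 1
    level_of_uniq = np.clip(level_of_uniq, 1, ng)
    return level_of_uniq[inverse].reshape(values.shape)


def quantize_roi(
    volume: ImageVolume,
    mask: ROIMask,
    ng: int = 64,
    k_sigma: float = 3.0,
    sigma_divisor: str = "n",
    crop: bool = True,
) -> QuantizedROI:
    """Normalize and quantize the masked voxels of a volume.

    Runs the fixed two-step pipeline (clip to ROI mean ± kσ, then
    histogram-equalize to ``ng`` levels) and returns a
    :class:`QuantizedROI` on the mask bounding box (``crop=True``) or the
    full grid.  Cropping never changes the result of any texture feature;
    it only trims empty planes.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    data = volume.data
    m = mask.data
    if crop:
        idx = np.nonzero(m)
        slices = tuple(
            slice(int(a.min()), int(a.max()) + 1) for a in idx
        )
        data = data[slices]
        m = m[slices]
    roi_values = data[m]
    normalized = collewet_normalize(roi_values, k_sigma=k_sigma, sigma_divisor=sigma_divisor)
    roi_levels = quantize_equalize(normalized, ng=ng)
    levels = np.zeros(m.shape, dtype=np.int64)
    levels[m] = roi_levels
    return QuantizedROI(levels=levels, mask=m, ng=ng, spacing=volume.spacing)
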