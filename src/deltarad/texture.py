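"""3D second-order texture matrices and the 39-feature vector.

Four matrix families are computed from a :class:`~deltarad.preprocessing.QuantizedROI`:

* **GLCM** — gray level co-occurrence matrix: joint probabilities of level
  pairs at a voxel offset, counted over the 13 unique 3D directions, both
  orderings (symmetric).
* **GLRLM** — gray level run length matrix: maximal collinear runs of equal
  level along the same 13 directions.
* **GLSZM** — gray level size zone matrix: maximal 26-connected components
  of equal level, counted by level and zone size.
* **NGTDM** — neighborhood gray tone difference matrix: per-level summed
  absolute deviation of a voxel's level from the mean level of its valid
  26-neighborhood.

Offsets live on the voxel lattice (distances in voxels, not mm); anisotropic
spacing is carried along but does not reweight offsets.

The canonical feature vector has exactly 39 entries: 8 GLCM + 13 GLRLM +
13 GLSZM + 5 NGTDM, in the order of :data:`FEATURE_NAMES`.  The headline
features are ``glcm_energy`` (angular second moment) and
``glszm_large_zone_emphasis``.

Degenerate-input conventions (documented, not errors, so longitudinal
series never crash mid-cohort):

* ROI with no co-occurring voxel pairs (e.g. a single voxel): the GLCM
  falls back to the diagonal distribution of the level histogram, so a
  lone voxel behaves like a perfectly homogeneous texture.
* ROI with no voxel owning a valid neighbor: all NGTDM features are 0,
  except coarseness which takes its conventional cap (1e6) since the
  texture is degenerately smooth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocessing import QuantizedROI

__all__ = [
    "GLCM",
    "GLRLM",
    "GLSZM",
    "NGTDM",
    "TextureConfig",
    "DIRECTIONS_3D",
    "FEATURE_NAMES",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
    "build_ngtdm",
    "extract_features",
    "glcm_energy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_variance",
    "glcm_sum_average",
    "glcm_entropy",
    "glcm_dissimilarity",
    "glszm_large_zone_emphasis",
]

#: The 13 unique 3D direction offsets (half of the 26-neighborhood).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_COARSENESS_CAP = 1.0e6  # conventional value for a perfectly smooth ROI

Aggregation = Literal["merged", "averaged"]


# --------------------------------------------------------------------------
# matrix containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCM:
    """Symmetric co-occurrence counts and probabilities over ``Ng`` levels."""

    counts: np.ndarray                     # Ng x Ng, merged over directions
    p: np.ndarray                          # normalized, sums to 1
    distance: int
    aggregation: Aggregation
    directions: tuple = DIRECTIONS_3D
    p_by_direction: Optional[tuple] = None  # set when aggregation == "averaged"

    @property
    def ng(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class GLRLM:
    """Run-length counts, levels x run length, merged or per-direction."""

    counts: np.ndarray                     # Ng x Rmax (column r-1 <-> length r)
    aggregation: Aggregation
    counts_by_direction: Optional[tuple] = None

    @property
    def n_runs(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class GLSZM:
    """Zone counts ``P(i, s)``: 26-connected equal-level components."""

    counts: np.ndarray                     # Ng x Smax (column s-1 <-> size s)

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class NGTDM:
    """Per-level occupancy ``n_i`` and summed neighborhood deviations ``s_i``."""

    s: np.ndarray                          # length Ng
    n: np.ndarray                          # length Ng, integer counts


@dataclass(frozen=True)
class TextureConfig:
    """Knobs for the texture stage; defaults follow the pipeline's protocol."""

    glcm_distance: int = 1
    glcm_aggregation: Aggregation = "merged"
    glrlm_aggregation: Aggregation = "merged"
    connectivity: int = 26  # fixed: 3D zones/neighborhoods use 26-connectivity


def _offset_slices(shape, offset):
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _glcm_counts_direction(levels, mask, offset, ng) -> np.ndarray:
    src, dst = _offset_slices(levels.shape, offset)
    a, b = levels[src], levels[dst]
    valid = mask[src] & mask[dst]
    counts = np.zeros((ng, ng), dtype=np.float64)
    i, j = a[valid] - 1, b[valid] - 1
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)      # count both orderings -> symmetric
    return counts


def _normalize_glcm(counts, levels, mask):
    total = counts.sum()
    if total > 0:
        return counts / total
    # no co-occurring pair (isolated voxels): diagonal level histogram
    hist = np.bincount(levels[mask] - 1, minlength=counts.shape[0]).astype(float)
    return np.diag(hist / hist.sum())


def build_glcm(
    q: QuantizedROI,
    distance: int = 1,
    aggregation: Aggregation = "merged",
) -> GLCM:
    """Co-occurrence matrix at the given Chebyshev voxel distance.

    Pairs with either voxel outside the ROI are excluded.  ``"merged"``
    sums counts over the 13 directions into one matrix before normalizing;
    ``"averaged"`` also keeps per-direction probability matrices so that
    features can be averaged across directions.
    """
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    levels, mask, ng = q.levels, q.mask, q.ng
    per_dir = [
        _glcm_counts_direction(levels, mask, tuple(distance * c for c in d), ng)
        for d in DIRECTIONS_3D
    ]
    merged = np.sum(per_dir, axis=0)
    p = _normalize_glcm(merged, levels, mask)
    p_by_direction = None
    if aggregation == "averaged":
        p_by_direction = tuple(_normalize_glcm(c, levels, mask) for c in per_dir)
    elif aggregation != "merged":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return GLCM(
        counts=merged,
        p=p,
        distance=distance,
        aggregation=aggregation,
        p_by_direction=p_by_direction,
    )


def _runs_direction(levels, mask, offset, ng) -> np.ndarray:
    """Run-length counts (Ng x Rmax) along one direction, vectorized walk."""
    shape = levels.shape
    # cont[x] = run continues from x to x + offset
    cont = np.zeros(shape, dtype=bool)
    src, dst = _offset_slices(shape, offset)
    cont[src] = mask[src] & mask[dst] & (levels[src] == levels[dst])
    # start voxels: in ROI with no same-level predecessor along -offset
    prev_cont = np.zeros(shape, dtype=bool)
    prev_cont[dst] = cont[src]
    starts = np.argwhere(mask & ~prev_cont)

    lengths = np.ones(len(starts), dtype=np.int64)
    run_levels = levels[tuple(starts.T)]
    pos = starts.copy()
    active = np.arange(len(starts))
    step = np.asarray(offset)
    while active.size:
        can_continue = cont[tuple(pos[active].T)]
        active = active[can_continue]
        pos[active] += step
        lengths[active] += 1

    rmax = int(lengths.max()) if len(lengths) else 1
    counts = np.zeros((ng, rmax), dtype=np.float64)
    np.add.at(counts, (run_levels - 1, lengths - 1), 1.0)
    return counts


def build_glrlm(
    q: QuantizedROI, aggregation: Aggregation = "merged"
) -> GLRLM:
    """Maximal equal-level runs along the 13 directions.

    A run is broken by the ROI boundary or a level change; every ROI voxel
    belongs to exactly one run per direction.
    """
    per_dir = [_runs_direction(q.levels, q.mask, d, q.ng) for d in DIRECTIONS_3D]
    rmax = max(c.shape[1] for c in per_dir)
    padded = [
        np.pad(c, ((0, 0), (0, rmax - c.shape[1]))) for c in per_dir
    ]
    merged = np.sum(padded, axis=0)
    if aggregation == "averaged":
        return GLRLM(counts=merged, aggregation="averaged",
                     counts_by_direction=tuple(per_dir))
    if aggregation != "merged":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return GLRLM(counts=merged, aggregation="merged")


def build_glszm(q: QuantizedROI) -> GLSZM:
    """Zones = maximal 26-connected components of equal-level ROI voxels."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    smax = 1
    for level in np.unique(q.roi_levels):
        labeled, n = ndimage.label(q.levels == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        sizes_by_level.append((int(level), sizes))
        smax = max(smax, int(sizes.max()))
    counts = np.zeros((q.ng, smax), dtype=np.float64)
    for level, sizes in sizes_by_level:
        np.add.at(counts, (level - 1, sizes - 1), 1.0)
    return GLSZM(counts=counts)


def build_ngtdm(q: QuantizedROI) -> NGTDM:
    """Summed |level - neighborhood mean| per level over the 26-neighborhood.

    Voxels with no ROI neighbor do not contribute (their ``n`` count is 0).
    """
    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    m = q.mask.astype(np.float64)
    nbr_count = ndimage.correlate(m, kernel, mode="constant", cval=0.0)
    nbr_sum = ndimage.correlate(q.levels * m, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nbr_count > 0.5)
    s = np.zeros(q.ng, dtype=np.float64)
    n = np.zeros(q.ng, dtype=np.int64)
    if valid.any():
        lev = q.levels[valid]
        diff = np.abs(lev - nbr_sum[valid] / nbr_count[valid])
        np.add.at(s, lev - 1, diff)
        np.add.at(n, lev - 1, 1)
    return NGTDM(s=s, n=n)


# --------------------------------------------------------------------------
# GLCM features
# --------------------------------------------------------------------------

def _glcm_apply(g: GLCM, fn: Callable[[np.ndarray], float]) -> float:
    if g.aggregation == "averaged":
        return float(np.mean([fn(p) for p in g.p_by_direction]))
    return float(fn(g.p))


def _level_grids(ng):
    i = np.arange(1, ng + 1, dtype=np.float64)
    return np.meshgrid(i, i, indexing="ij")


def _p_energy(p):
    return float(np.sum(p * p))


def _p_contrast(p):
    ii, jj = _level_grids(p.shape[0])
    return float(np.sum((ii - jj) ** 2 * p))


def _p_correlation(p):
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    var = float(np.sum((i - mu) ** 2 * px))
    if var <= 0:
        return 1.0  # single-level texture: perfectly correlated by convention
    ii, jj = _level_grids(ng)
    return float(np.sum((ii - mu) * (jj - mu) * p) / var)


def _p_homogeneity(p):
    ii, jj = _level_grids(p.shape[0])
    return float(np.sum(p / (1.0 + np.abs(ii - jj))))


def _p_variance(p):
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    return float(np.sum((i - mu) ** 2 * px))


def _p_sum_average(p):
    ii, jj = _level_grids(p.shape[0])
    return float(np.sum((ii + jj) * p))


def _p_entropy(p):
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _p_dissimilarity(p):
    ii, jj = _level_grids(p.shape[0])
    return float(np.sum(np.abs(ii - jj) * p))


def glcm_energy(g: GLCM) -> float:
    """Angular second moment, ``sum p(i,j)^2``; 1 iff one cell carries all mass."""
    return _glcm_apply(g, _p_energy)


def glcm_contrast(g: GLCM) -> float:
    return _glcm_apply(g, _p_contrast)


def glcm_correlation(g: GLCM) -> float:
    return _glcm_apply(g, _p_correlation)


def glcm_homogeneity(g: GLCM) -> float:
    """Inverse difference, ``sum p/(1+|i-j|)``."""
    return _glcm_apply(g, _p_homogeneity)


def glcm_variance(g: GLCM) -> float:
    return _glcm_apply(g, _p_variance)


def glcm_sum_average(g: GLCM) -> float:
    return _glcm_apply(g, _p_sum_average)


def glcm_entropy(g: GLCM) -> float:
    return _glcm_apply(g, _p_entropy)


def glcm_dissimilarity(g: GLCM) -> float:
    return _glcm_apply(g, _p_dissimilarity)


# --------------------------------------------------------------------------
# run/zone matrix features (shared formula family)
# --------------------------------------------------------------------------

def _rz_features(counts: np.ndarray) -> dict[str, float]:
    """The 13 classic run-length-style features for a level x size matrix."""
    ng, smax = counts.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, smax + 1, dtype=np.float64)[None, :]
    n = counts.sum()
    voxel_mass = float(np.sum(s * counts))   # total voxel incidence
    ri = counts.sum(axis=1)                  # per-level totals
    rs = counts.sum(axis=0)                  # per-size totals
    i1 = i.ravel()
    s1 = s.ravel()
    mu_i = float(np.sum(i1 * ri) / n)
    mu_s = float(np.sum(s1 * rs) / n)
    return {
        "small": float(np.sum(counts / s**2) / n),
        "large": float(np.sum(counts * s**2) / n),
        "gln": float(np.sum(ri**2) / n),
        "szn": float(np.sum(rs**2) / n),
        "pct": float(n / voxel_mass),
        "lgl": float(np.sum(counts / i**2) / n),
        "hgl": float(np.sum(counts * i**2) / n),
        "slgl": float(np.sum(counts / (i**2 * s**2)) / n),
        "shgl": float(np.sum(counts * i**2 / s**2) / n),
        "llgl": float(np.sum(counts * s**2 / i**2) / n),
        "lhgl": float(np.sum(counts * i**2 * s**2) / n),
        "glv": float(np.sum((i1 - mu_i) ** 2 * ri) / n),
        "sv": float(np.sum((s1 - mu_s) ** 2 * rs) / n),
    }


_GLRLM_KEYS = {
    "glrlm_short_run_emphasis": "small",
    "glrlm_long_run_emphasis": "large",
    "glrlm_gray_level_nonuniformity": "gln",
    "glrlm_run_length_nonuniformity": "szn",
    "glrlm_run_percentage": "pct",
    "glrlm_low_gray_level_run_emphasis": "lgl",
    "glrlm_high_gray_level_run_emphasis": "hgl",
    "glrlm_short_run_low_gray_level_emphasis": "slgl",
    "glrlm_short_run_high_gray_level_emphasis": "shgl",
    "glrlm_long_run_low_gray_level_emphasis": "llgl",
    "glrlm_long_run_high_gray_level_emphasis": "lhgl",
    "glrlm_gray_level_variance": "glv",
    "glrlm_run_length_variance": "sv",
}

_GLSZM_KEYS = {
    "glszm_small_zone_emphasis": "small",
    "glszm_large_zone_emphasis": "large",
    "glszm_gray_level_nonuniformity": "gln",
    "glszm_zone_size_nonuniformity": "szn",
    "glszm_zone_percentage": "pct",
    "glszm_low_gray_level_zone_emphasis": "lgl",
    "glszm_high_gray_level_zone_emphasis": "hgl",
    "glszm_small_zone_low_gray_level_emphasis": "slgl",
    "glszm_small_zone_high_gray_level_emphasis": "shgl",
    "glszm_large_zone_low_gray_level_emphasis": "llgl",
    "glszm_large_zone_high_gray_level_emphasis": "lhgl",
    "glszm_gray_level_variance": "glv",
    "glszm_zone_size_variance": "sv",
}


def glrlm_features(r: GLRLM) -> dict[str, float]:
    if r.aggregation == "averaged":
        per_dir = [_rz_features(c) for c in r.counts_by_direction]
        raw = {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}
    else:
        raw = _rz_features(r.counts)
    return {name: raw[key] for name, key in _GLRLM_KEYS.items()}


def glszm_features(z: GLSZM) -> dict[str, float]:
    raw = _rz_features(z.counts)
    return {name: raw[key] for name, key in _GLSZM_KEYS.items()}


def glszm_large_zone_emphasis(z: GLSZM) -> float:
    """``(1/Nz) sum P(i,s) s^2``; >= 1, equality iff all zones are singletons."""
    if z.n_zones < 1:
        raise ValueError("GLSZM has no zones")
    s = np.arange(1, z.counts.shape[1] + 1, dtype=np.float64)[None, :]
    return float(np.sum(z.counts * s**2) / z.n_zones)


# --------------------------------------------------------------------------
# NGTDM features
# --------------------------------------------------------------------------

def ngtdm_features(t: NGTDM) -> dict[str, float]:
    """Amadasun–King texture descriptors; all-zero ``n`` yields the
    documented degenerate values (0, coarseness capped)."""
    n_total = float(t.n.sum())
    out = {
        "ngtdm_coarseness": 0.0,
        "ngtdm_contrast": 0.0,
        "ngtdm_busyness": 0.0,
        "ngtdm_complexity": 0.0,
        "ngtdm_strength": 0.0,
    }
    if n_total == 0:
        return out
    present = t.n > 0
    i = np.arange(1, len(t.n) + 1, dtype=np.float64)[present]
    p = t.n[present] / n_total
    s = t.s[present]
    ngp = int(present.sum())

    psi = float(np.sum(p * s))
    out["ngtdm_coarseness"] = 1.0 / psi if psi > 0 else _COARSENESS_CAP

    if ngp > 1:
        dij2 = (i[:, None] - i[None, :]) ** 2
        out["ngtdm_contrast"] = float(
            np.sum(p[:, None] * p[None, :] * dij2)
            / (ngp * (ngp - 1))
            * (s.sum() / n_total)
        )
        ip = i * p
        denom = float(np.sum(np.abs(ip[:, None] - ip[None, :])))
        out["ngtdm_busyness"] = psi / denom if denom > 0 else 0.0
        absdij = np.abs(i[:, None] - i[None, :])
        ps = p * s
        out["ngtdm_complexity"] = float(
            np.sum(absdij * (ps[:, None] + ps[None, :]) / (p[:, None] + p[None, :]))
            / n_total
        )
        s_sum = float(s.sum())
        if s_sum > 0:
            out["ngtdm_strength"] = float(
                np.sum((p[:, None] + p[None, :]) * dij2) / s_sum
            )
    return out


# --------------------------------------------------------------------------
# the canonical 39-feature vector
# --------------------------------------------------------------------------

_GLCM_FEATURES: dict[str, Callable[[GLCM], float]] = {
    "glcm_energy": glcm_energy,
    "glcm_contrast": glcm_contrast,
    "glcm_correlation": glcm_correlation,
    "glcm_homogeneity": glcm_homogeneity,
    "glcm_variance": glcm_variance,
    "glcm_sum_average": glcm_sum_average,
    "glcm_entropy": glcm_entropy,
    "glcm_dissimilarity": glcm_dissimilarity,
}

#: Canonical ordering of the 39 features (8 GLCM, 13 GLRLM, 13 GLSZM, 5 NGTDM).
FEATURE_NAMES: tuple[str, ...] = (
    tuple(_GLCM_FEATURES)
    + tuple(_GLRLM_KEYS)
    + tuple(_GLSZM_KEYS)
    + ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
       "ngtdm_complexity", "ngtdm_strength")
)

assert len(FEATURE_NAMES) == 39


def extract_features(
    q: QuantizedROI, config: TextureConfig | None = None
) -> pd.Series:
    """Compute the canonical 39-feature texture vector for one ROI.

    Returns a :class:`pandas.Series` indexed by :data:`FEATURE_NAMES`
    (fixed order).  Deterministic: the same ROI always yields a
    bit-identical vector.
    """
    config = config or TextureConfig()
    g = build_glcm(q, distance=config.glcm_distance,
                   aggregation=config.glcm_aggregation)
    r = build_glrlm(q, aggregation=config.glrlm_aggregation)
    z = build_glszm(q)
    t = build_ngtdm(q)

    values: dict[str, float] = {}
    for name, fn in _GLCM_FEATURES.items():
        values[name] = fn(g)
    values.update(glrlm_features(r))
    values.update(glszm_features(z))
    values.update(ngtdm_features(t))

    vec = pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES),
                    dtype=np.float64)
    if not np.all(np.isfinite(vec.to_numpy())):
        bad = vec.index[~np.isfinite(vec.to_numpy())].tolist()
        raise AssertionError(f"non-finite texture features: {bad}")
    return vec
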