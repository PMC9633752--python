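"""Biologically effective dose bookkeeping and delta features.

SBRT courses in the cohort use heterogeneous fractionations (30-60 Gy in
3-5 fractions), so "after fraction k" means different biological doses for
different patients.  Checkpoints are therefore defined on the linear-
quadratic biologically effective dose

    BED = n * d * (1 + d / (alpha/beta)),   d = dose per fraction,

with alpha/beta = 10 Gy for tumor.  Setup image k is acquired *before*
delivering fraction k, so the cumulative BED realized at image k is
``(k - 1) * d * (1 + d / ab)``.  A checkpoint (20 or 40 Gy BED) is realized
by the first setup image acquired at or after that cumulative BED; a course
that never accumulates the target BED before its last image is flagged
unreachable for that checkpoint and excluded from that feature library only.

Delta features are checkpoint minus baseline, elementwise over the 39
texture features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io import ImageVolume, ROIMask
from .preprocessing import quantize_roi
from .texture import FEATURE_NAMES, TextureConfig, extract_features

__all__ = [
    "TreatmentCourse",
    "BEDCheckpoint",
    "DeltaFeatureTable",
    "compute_bed",
    "align_checkpoint",
    "delta_features",
    "extract_course_features",
    "build_delta_table",
]

DEFAULT_ALPHA_BETA = 10.0  # Gy, tumor


def compute_bed(total_dose: float, n_fractions: int,
                alpha_beta: float = DEFAULT_ALPHA_BETA) -> float:
    """Linear-quadratic BED of an equally fractionated course, in Gy.

    ``n * d * (1 + d/alpha_beta)`` with ``d = total_dose / n_fractions``.
    Converges to the physical dose as ``alpha_beta -> inf``.
    """
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    if alpha_beta <= 0:
        raise ValueError(f"alpha_beta must be > 0, got {alpha_beta}")
    if total_dose < 0:
        raise ValueError(f"total_dose must be >= 0, got {total_dose}")
    d = total_dose / n_fractions
    return n_fractions * d * (1.0 + d / alpha_beta)


@dataclass
class TreatmentCourse:
    """One patient's fractionation plus the ordered pre-fraction images.

    ``images[k]`` is ``(fraction_index, volume, mask)`` with the image
    acquired before delivering fraction ``fraction_index`` (1-based); the
    fraction-1 image is the pre-treatment baseline.
    """

    patient_id: str
    rx_dose: float
    n_fractions: int
    alpha_beta: float = DEFAULT_ALPHA_BETA
    images: list[tuple[int, ImageVolume, ROIMask]] = field(default_factory=list)

    def __post_init__(self):
        if self.rx_dose <= 0 or self.n_fractions < 1:
            raise ValueError("invalid prescription")
        indices = [k for k, _, _ in self.images]
        if indices != sorted(indices):
            raise ValueError("images must be ordered by fraction index")
        if any(k < 1 for k in indices):
            raise ValueError("fraction indices are 1-based")

    @property
    def dose_per_fraction(self) -> float:
        return self.rx_dose / self.n_fractions

    @property
    def bed_per_fraction(self) -> float:
        d = self.dose_per_fraction
        return d * (1.0 + d / self.alpha_beta)

    def cumulative_bed_before(self, fraction_index: int) -> float:
        """BED delivered before the setup image of fraction ``fraction_index``."""
        return (fraction_index - 1) * self.bed_per_fraction


@dataclass(frozen=True)
class BEDCheckpoint:
    """Which setup image realizes a target cumulative BED."""

    target_bed: float
    image_index: Optional[int]        # fraction index; None if unreachable
    realized_bed: Optional[float]

    @property
    def reachable(self) -> bool:
        return self.image_index is not None


def align_checkpoint(course: TreatmentCourse, target_bed: float) -> BEDCheckpoint:
    """First setup image acquired at or after ``target_bed`` cumulative BED.

    Uses the ceiling rule: ``image_index`` is the smallest fraction index k
    with ``(k-1) * BED/Fx >= target_bed``.  Only fraction indices actually
    present in ``course.images`` qualify; if none does, the checkpoint is
    unreachable (a reported state, not an exception).
    """
    candidates = [
        (k, course.cumulative_bed_before(k))
        for k, _, _ in course.images
        if course.cumulative_bed_before(k) >= target_bed - 1e-9
    ]
    if not candidates:
        return BEDCheckpoint(target_bed=target_bed, image_index=None,
                             realized_bed=None)
    k, realized = min(candidates)
    return BEDCheckpoint(target_bed=target_bed, image_index=k,
                         realized_bed=realized)


def delta_features(baseline: pd.Series, at_checkpoint: pd.Series) -> pd.Series:
    """Elementwise ``checkpoint - baseline`` over the 39 named features.

    Both vectors must carry the same features in the same order.
    """
    if len(baseline) != len(at_checkpoint):
        raise ValueError("feature vectors differ in length")
    if list(baseline.index) != list(at_checkpoint.index):
        raise ValueError("feature vectors differ in feature order")
    return at_checkpoint - baseline


def extract_course_features(
    course: TreatmentCourse,
    config: TextureConfig | None = None,
    ng: int = 64,
    k_sigma: float = 3.0,
) -> dict[int, pd.Series]:
    """Texture features per setup image of one course, keyed by fraction index."""
    out = {}
    for k, vol, mask in course.images:
        q = quantize_roi(vol, mask, ng=ng, k_sigma=k_sigma)
        out[k] = extract_features(q, config=config)
    return out


@dataclass
class DeltaFeatureTable:
    """Per-checkpoint delta-feature library plus its exclusion report."""

    checkpoint: float                 # target BED, Gy
    table: pd.DataFrame               # index patient_id; 39 delta columns +
                                      # image_index, realized_bed
    excluded: pd.DataFrame            # patient_id, reason

    def feature_matrix(self) -> pd.DataFrame:
        return self.table[list(FEATURE_NAMES)]


def build_delta_table(
    courses: Sequence[TreatmentCourse],
    target_beds: Sequence[float] = (20.0, 40.0),
    config: TextureConfig | None = None,
    ng: int = 64,
    k_sigma: float = 3.0,
    precomputed: Optional[dict[str, dict[int, pd.Series]]] = None,
) -> dict[float, DeltaFeatureTable]:
    """Delta-feature library per target BED checkpoint.

    Every course must include its fraction-1 (baseline) image.  Patients
    whose course never reaches a checkpoint appear in that library's
    exclusion report instead of its table.  ``precomputed`` may supply
    per-course feature vectors (as from :func:`extract_course_features`)
    to avoid re-extracting when building several libraries.
    """
    features_by_patient: dict[str, dict[int, pd.Series]] = {}
    for course in courses:
        indices = [k for k, _, _ in course.images]
        if 1 not in indices:
            raise ValueError(
                f"patient {course.patient_id}: missing baseline (fraction-1) image"
            )
        if precomputed and course.patient_id in precomputed:
            features_by_patient[course.patient_id] = precomputed[course.patient_id]
        else:
            features_by_patient[course.patient_id] = extract_course_features(
                course, config=config, ng=ng, k_sigma=k_sigma
            )

    libraries: dict[float, DeltaFeatureTable] = {}
    for target in target_beds:
        rows, excluded = [], []
        for course in courses:
            cp = align_checkpoint(course, target)
            if not cp.reachable:
                max_bed = max(
                    (course.cumulative_bed_before(k) for k, _, _ in course.images),
                    default=0.0,
                )
                excluded.append(
                    {
                        "patient_id": course.patient_id,
                        "reason": f"max cumulative BED before an image "
                                  f"{max_bed:g} Gy < target {target:g} Gy",
                    }
                )
                continue
            feats = features_by_patient[course.patient_id]
            delta = delta_features(feats[1], feats[cp.image_index])
            row = {"patient_id": course.patient_id,
                   "image_index": cp.image_index,
                   "realized_bed": cp.realized_bed}
            row.update(delta.to_dict())
            rows.append(row)
        cols = ["patient_id", "image_index", "realized_bed", *FEATURE_NAMES]
        table = pd.DataFrame(rows, columns=cols).set_index("patient_id")
        libraries[target] = DeltaFeatureTable(
            checkpoint=target,
            table=table,
            excluded=pd.DataFrame(excluded, columns=["patient_id", "reason"]),
        )
    return libraries
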