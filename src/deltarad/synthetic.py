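"""Synthetic longitudinal cohorts for exercising the pipeline end to end.

No patient images are distributed with the study, so the package ships a
generator that emulates the *structure* of the data: per-fraction 3D setup
volumes of an ellipsoidal liver lesion whose texture evolves differently
for responders and poor responders, plus matching clinical covariates and
fractionation schedules drawn from the study's menu.

The texture control knob is the correlation length of a Gaussian random
field.  A longer correlation length produces larger uniform regions after
quantization, which raises both GLCM energy and GLSZM large zone emphasis;
it is an engineered surrogate for "texture homogeneity", not a claim about
tumor biology.  The class trajectories follow the observed pattern:
lesions under local control become more homogeneous by the 20 Gy BED
checkpoint and relax back by 40 Gy BED, while locally progressing lesions
do the opposite.  The per-class trajectory multipliers are applied to the
baseline correlation length by piecewise-linear interpolation in
cumulative BED through the nodes (0 Gy, 1), (20 Gy, m20), (40 Gy, m40).

All generators are seed-deterministic: the same spec and seed reproduce
every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .bed import TreatmentCourse, compute_bed
from .io import ImageVolume, PatientRecord, ROIMask
from .texture import FEATURE_NAMES

__all__ = [
    "SyntheticCohortSpec",
    "SCHEDULE_MENU",
    "trajectory_multiplier",
    "generate_lesion_image",
    "generate_cohort",
    "generate_feature_table",
    "generate_clinical_covariates",
]

#: Distinct (rx_dose Gy, n_fractions) schedules appearing in the study cohort.
SCHEDULE_MENU: tuple[tuple[float, int], ...] = (
    (50.0, 5), (45.0, 5), (40.0, 4), (30.0, 5), (60.0, 5), (54.0, 3), (30.0, 3),
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Conditions of the emulated study cohort.

    Defaults copy the study's shape: 22 patients, 7 with poor response,
    1.5 x 1.5 x 3.0 mm voxels, schedules sampled from the cohort's menu.
    The lesion occupies several hundred voxels so zone statistics are
    non-degenerate on a desk-scale grid.
    """

    n_patients: int = 22
    n_poor_responders: int = 7
    shape: tuple[int, int, int] = (48, 48, 16)
    spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    # ellipsoid semi-axis ranges, mm
    radius_xy_mm: tuple[float, float] = (11.0, 15.0)
    radius_z_mm: tuple[float, float] = (8.0, 11.0)
    schedule_menu: tuple[tuple[float, int], ...] = SCHEDULE_MENU
    ell0_mm: float = 2.5                 # baseline texture correlation length
    m20_responder: float = 2.0           # homogeneity rises by BED 20 ...
    m40_responder: float = 1.15          # ... and falls back toward baseline
    m20_poor: float = 0.5                # poor responders: opposite trajectory
    m40_poor: float = 0.85
    noise_sd: float = 0.15               # white noise relative to unit field SD
    alpha_beta: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_poor_responders < self.n_patients:
            raise ValueError("need 0 < n_poor_responders < n_patients")
        if self.ell0_mm <= 0:
            raise ValueError("ell0_mm must be > 0")
        for m in (self.m20_responder, self.m40_responder,
                  self.m20_poor, self.m40_poor):
            if m <= 0:
                raise ValueError("trajectory multipliers must be > 0")


def trajectory_multiplier(spec: SyntheticCohortSpec, poor_responder: bool,
                          cum_bed: float) -> float:
    """Correlation-length multiplier at a cumulative BED (Gy).

    Piecewise-linear through (0, 1), (20, m20), (40, m40); constant beyond
    40 Gy BED.
    """
    if poor_responder:
        m20, m40 = spec.m20_poor, spec.m40_poor
    else:
        m20, m40 = spec.m20_responder, spec.m40_responder
    return float(np.interp(cum_bed, [0.0, 20.0, 40.0], [1.0, m20, m40]))


def _patient_rng(spec: SyntheticCohortSpec, patient_index: int,
                 stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, patient_index, stream])
    )


def _lesion_mask(spec: SyntheticCohortSpec,
                 rng: np.random.Generator) -> ROIMask:
    rx = rng.uniform(*spec.radius_xy_mm)
    ry = rng.uniform(*spec.radius_xy_mm)
    rz = rng.uniform(*spec.radius_z_mm)
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    half = (nx * dx / 2, ny * dy / 2, nz * dz / 2)
    if rx >= half[0] or ry >= half[1] or rz >= half[2]:
        raise ValueError("lesion semi-axes exceed the image grid")
    x = (np.arange(nx) + 0.5) * dx - half[0]
    y = (np.arange(ny) + 0.5) * dy - half[1]
    z = (np.arange(nz) + 0.5) * dz - half[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    inside = (X / rx) ** 2 + (Y / ry) ** 2 + (Z / rz) ** 2 <= 1.0
    return ROIMask(data=inside, spacing=spec.spacing)


def _smoothed_field(spec: SyntheticCohortSpec, white: np.ndarray,
                    ell_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ``ell_mm``."""
    sigma_vox = [max(ell_mm / s, 1e-6) for s in spec.spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_lesion_image(
    spec: SyntheticCohortSpec,
    patient_index: int,
    cum_bed: float,
    poor_responder: bool,
    timepoint: int = 0,
) -> tuple[ImageVolume, ROIMask]:
    """One setup image + mask for a patient at a cumulative BED.

    Longitudinal structure: the lesion geometry and the underlying white
    field are fixed per patient, so consecutive setup images show the same
    anatomy; only the correlation length (scaled by the class trajectory at
    ``cum_bed``) and a fresh per-timepoint observation noise draw change.
    With ``noise_sd = 0`` and a unit trajectory multiplier, every timepoint
    reproduces the baseline image exactly.  Intensities are offset/scaled
    into an arbitrary positive MR-like range.
    """
    mask = _lesion_mask(spec, _patient_rng(spec, patient_index, 0))
    white = _patient_rng(spec, patient_index, 1).standard_normal(spec.shape)
    mult = trajectory_multiplier(spec, poor_responder, cum_bed)
    field = _smoothed_field(spec, white, spec.ell0_mm * mult)
    if spec.noise_sd > 0:
        noise_rng = _patient_rng(spec, patient_index, 100 + timepoint)
        field = field + spec.noise_sd * noise_rng.standard_normal(spec.shape)
    data = 100.0 + 20.0 * field
    return ImageVolume(data=data, spacing=spec.spacing), mask


def generate_cohort(
    spec: SyntheticCohortSpec | None = None,
) -> tuple[list[TreatmentCourse], list[PatientRecord]]:
    """A full longitudinal cohort: per-fraction images plus patient records.

    Schedules are drawn from the study menu, labels assign the first
    ``n_poor_responders`` patients (after a seeded shuffle) to the poor-
    response class, and every course carries one setup image per fraction
    (image k acquired before fraction k).
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10**6]))
    labels = np.zeros(spec.n_patients, dtype=bool)
    labels[: spec.n_poor_responders] = True
    rng.shuffle(labels)

    courses, records = [], []
    for idx in range(spec.n_patients):
        pid = f"SYN{idx + 1:03d}"
        rx_dose, n_fx = spec.schedule_menu[
            rng.integers(0, len(spec.schedule_menu))
        ]
        course = TreatmentCourse(
            patient_id=pid, rx_dose=rx_dose, n_fractions=n_fx,
            alpha_beta=spec.alpha_beta,
        )
        for k in range(1, n_fx + 1):
            cum_bed = course.cumulative_bed_before(k)
            vol, mask = generate_lesion_image(
                spec, idx, cum_bed, bool(labels[idx]), timepoint=k
            )
            course.images.append((k, vol, mask))
        courses.append(course)

        geom = _patient_rng(spec, idx, 2 * 10**6)
        records.append(
            PatientRecord(
                patient_id=pid,
                poor_response=bool(labels[idx]),
                age=float(geom.integers(49, 95)),
                rx_dose=rx_dose,
                n_fractions=n_fx,
                tumor_size=float(np.round(geom.uniform(1.3, 8.0), 1)),
                diagnosis=str(geom.choice(["HCC", "ICC", "LM"])),
            )
        )
    return courses, records


def generate_feature_table(
    n: int = 22,
    class_counts: tuple[int, int] = (15, 7),
    planted_features: Sequence[str] = (),
    effect_size: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Table-level surrogate: 39 standard-normal delta columns, planted shift.

    ``class_counts = (n_control, n_poor)`` must sum to ``n``.  Planted
    columns are shifted by ``+effect_size/2`` for controls and
    ``-effect_size/2`` for poor responders (class means ``effect_size``
    standard deviations apart, responders up / progressors down, matching
    the observed trajectory opposition).  Returns the delta table and the
    boolean poor-response labels.
    """
    if sum(class_counts) != n:
        raise ValueError("class_counts must sum to n")
    unknown = set(planted_features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown feature names: {sorted(unknown)}")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((n, 39)), columns=list(FEATURE_NAMES)
    )
    y = np.zeros(n, dtype=bool)
    y[class_counts[0]:] = True          # poor responders
    for name in planted_features:
        X.loc[~y, name] += effect_size / 2.0
        X.loc[y, name] -= effect_size / 2.0
    return X, y


def generate_clinical_covariates(
    n: int,
    seed: int = 0,
    informative: bool = False,
    labels: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Cohort-like clinical covariates, optionally tied to the labels.

    Ages span 49-94, schedules come from the study menu (every schedule
    reaches the 20 Gy BED checkpoint before its last setup image), sizes
    span 1.3-8 cm.  With ``informative=True`` the tumor size is shifted up
    by 2 cm for poor responders; otherwise covariates are independent of
    any labels.
    """
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(
            columns=["age", "rx_dose", "n_fractions", "total_bed",
                     "bed_per_fx", "tumor_size", "sex", "ethnicity",
                     "kps", "cirrhosis"]
        )
    sched_idx = rng.integers(0, len(SCHEDULE_MENU), size=n)
    rx = np.array([SCHEDULE_MENU[i][0] for i in sched_idx])
    nfx = np.array([SCHEDULE_MENU[i][1] for i in sched_idx])
    total_bed = np.array([compute_bed(r, int(k)) for r, k in zip(rx, nfx)])
    size = np.round(rng.uniform(1.3, 8.0, size=n), 1)
    if informative:
        if labels is None:
            raise ValueError("informative covariates require labels")
        size = size + 2.0 * np.asarray(labels, dtype=float)
    df = pd.DataFrame(
        {
            "age": rng.integers(49, 95, size=n).astype(float),
            "rx_dose": rx,
            "n_fractions": nfx,
            "total_bed": total_bed,
            "bed_per_fx": total_bed / nfx,
            "tumor_size": size,
            "sex": rng.choice(["F", "M"], size=n),
            "ethnicity": rng.choice(["A", "B", "C"], size=n),
            "kps": rng.choice([70.0, 80.0, 90.0, 100.0], size=n),
            "cirrhosis": rng.integers(0, 2, size=n).astype(bool),
        }
    )
    return df
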