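"""Multi-contrast sagittal spine phantoms with graded pathologies.

The simulator emulates the statistical structure a fat-saturation synthesis
model has to learn, not anatomy or scanner physics. Each voxel belongs to one
of seven tissues (background, vertebral body, intervertebral disc, spinal
cord, CSF, paravertebral fat, paravertebral muscle). A tissue is a
three-compartment mixture — fat fraction, fluid fraction, and a base signal —
and each contrast is a fixed linear weighting of those compartments:

* T1-w: fat bright, fluid dark-ish;
* non-fs T2-w: fat and fluid both bright;
* T2-w fs: the fat weight is exactly zero, so adipose signal is suppressed
  while fluid (edema, CSF) stays bright.

Pathologies are ellipsoidal lesions clipped to their parent structure. An
edema-carrying lesion swaps fat signal for fluid signal inside its mask, so
it is bright on both T2-w contrasts and iso-to-dark on T1-w — the pattern
that makes fat-saturated images diagnostically valuable. Every lesion carries
a ground-truth grade on the six-pathology grading schema used downstream by
the reader-agreement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rigid import RigidTransform2D, apply_rigid_inplane
from .volumes import ContrastVolume

# ---------------------------------------------------------------------------
# tissue labels and signal model
# ---------------------------------------------------------------------------

BACKGROUND, VERTEBRA, DISC, CORD, CSF, FAT, MUSCLE = range(7)

LABEL_NAMES = {
    BACKGROUND: "background", VERTEBRA: "vertebral_body", DISC: "disc",
    CORD: "spinal_cord", CSF: "csf", FAT: "paravertebral_fat",
    MUSCLE: "paravertebral_muscle",
}


@dataclass(frozen=True)
class TissueParams:
    """Compartment mixture for one tissue: fractions in [0, 1], fat+fluid <= 1."""

    fat_fraction: float
    fluid_fraction: float
    base_signal: float

    def __post_init__(self) -> None:
        if not (0 <= self.fat_fraction <= 1 and 0 <= self.fluid_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fat_fraction + self.fluid_fraction > 1 + 1e-12:
            raise ValueError("fat_fraction + fluid_fraction must not exceed 1")
        if self.base_signal < 0:
            raise ValueError("base_signal must be non-negative")


DEFAULT_TISSUES: dict[int, TissueParams] = {
    BACKGROUND: TissueParams(0.0, 0.0, 0.0),
    VERTEBRA: TissueParams(0.5, 0.1, 0.1),     # fatty adult marrow
    DISC: TissueParams(0.0, 0.6, 0.1),
    CORD: TissueParams(0.0, 0.25, 0.25),
    CSF: TissueParams(0.0, 1.0, 0.0),
    FAT: TissueParams(0.95, 0.0, 0.02),
    MUSCLE: TissueParams(0.05, 0.2, 0.25),
}

#: (fat, fluid, base) weight per contrast. T2FS carries a fat weight of 0:
#: that zero IS the fat-suppression contract.
CONTRAST_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "T1": (1.0, 0.15, 1.0),
    "T2": (0.9, 1.0, 1.0),
    "T2FS": (0.0, 1.0, 1.0),
}

# ---------------------------------------------------------------------------
# pathology grading schema
# ---------------------------------------------------------------------------

PATHOLOGY_KINDS = (
    "bone_marrow_abnormality",
    "spondylodiscitis_expansion",
    "modic_type1",
    "vertebral_fracture",
    "cord_lesion",
    "paravertebral_abnormality",
)

#: Legal grade range per pathology kind (inclusive).
GRADE_RANGES: dict[str, tuple[int, int]] = {
    "bone_marrow_abnormality": (0, 4),
    "spondylodiscitis_expansion": (0, 3),
    "modic_type1": (0, 1),
    "vertebral_fracture": (0, 2),   # 1 = acute (edema), 2 = chronic
    "cord_lesion": (0, 1),
    "paravertebral_abnormality": (0, 3),  # 1 inflammation, 2 hematoma, 3 other
}

#: Extent boundary below which a marrow lesion counts as "focal" (grade 1)
#: rather than one-third of the body (grade 2). The thirds are grade
#: boundaries; the focal cutoff is this package's choice.
FOCAL_EXTENT = 0.10
ONE_THIRD = 1.0 / 3.0
TWO_THIRDS = 2.0 / 3.0


def _extent_grade_bone_marrow(extent: float) -> int:
    if extent <= 0:
        return 0
    if extent < FOCAL_EXTENT:
        return 1
    if extent <= ONE_THIRD:
        return 2
    if extent <= TWO_THIRDS:
        return 3
    return 4


def _extent_grade_spondylodiscitis(extent: float) -> int:
    if extent <= 0:
        return 0
    if extent <= ONE_THIRD:
        return 1
    if extent <= TWO_THIRDS:
        return 2
    return 3


@dataclass
class PathologyAnnotation:
    """One lesion: voxel mask, extent of the affected body, acuity, GT grade."""

    kind: str
    mask: np.ndarray                 # boolean, same shape as scene labels
    extent_fraction: float           # of the affected vertebral body, in [0, 1]
    edema: bool                      # fluid-bright on T2/T2FS when True
    gt_grade: int
    vertebra_index: int | None = None
    subtype: int | None = None       # paravertebral: 1/2/3

    def __post_init__(self) -> None:
        if self.kind not in PATHOLOGY_KINDS:
            raise ValueError(f"unknown pathology kind {self.kind!r}")
        lo, hi = GRADE_RANGES[self.kind]
        if not lo <= self.gt_grade <= hi:
            raise ValueError(f"grade {self.gt_grade} out of range [{lo}, {hi}] "
                             f"for {self.kind}")
        if not 0 <= self.extent_fraction <= 1:
            raise ValueError("extent_fraction must lie in [0, 1]")


@dataclass
class PhantomScene:
    """Tissue-label volume, per-tissue signal parameters, graded lesions."""

    labels: np.ndarray
    tissue_params: dict[int, TissueParams]
    pathologies: list[PathologyAnnotation]
    spacing: tuple[float, float, float]
    seed: int
    n_vertebrae: int = 0
    vertebra_masks: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for ann in self.pathologies:
            if ann.mask.shape != self.labels.shape:
                raise ValueError("pathology mask shape does not match label volume")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _build_labels(shape: tuple[int, int, int], n_vertebrae: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    S, H, W = shape
    if W < 32 or H < 24 or S < 3:
        raise ValueError(f"shape {shape} too small for a spine phantom")
    margin = 2
    disc_h = max(2, round(0.04 * H))
    body_h = (H - 2 * margin - (n_vertebrae - 1) * disc_h) // n_vertebrae
    if body_h < 4:
        raise ValueError(
            f"cannot fit {n_vertebrae} vertebrae into {H} rows: "
            "vertebral bodies would be under 4 voxels tall")

    labels = np.full(shape, MUSCLE, dtype=np.int16)
    labels[:, :margin, :] = BACKGROUND
    labels[:, H - margin:, :] = BACKGROUND

    a0 = round(0.15 * W)                      # anterior muscle | body boundary
    body_w = round(0.30 * W)
    csf_w = max(1, round(0.03 * W))
    cord_w = max(2, round(0.06 * W))
    fat_w = max(2, round(0.12 * W))

    body_masks = [np.zeros(shape, dtype=bool) for _ in range(n_vertebrae)]
    top = margin + (H - 2 * margin - n_vertebrae * body_h
                    - (n_vertebrae - 1) * disc_h) // 2
    for k in range(S):
        jitter = int(rng.integers(-1, 2))     # per-slice boundary wobble
        b0, b1 = a0 + jitter, a0 + jitter + body_w
        c0 = b1 + csf_w
        c1 = c0 + cord_w
        f0 = c1 + csf_w
        f1 = min(W - 1, f0 + fat_w)
        col = labels[k]
        col[margin:H - margin, b0:b1] = DISC  # gaps between bodies stay disc
        row = top
        for v in range(n_vertebrae):
            col[row:row + body_h, b0:b1] = VERTEBRA
            body_masks[v][k, row:row + body_h, b0:b1] = True
            row += body_h + disc_h
        col[margin:H - margin, b1:c0] = CSF
        col[margin:H - margin, c0:c1] = CORD
        col[margin:H - margin, c1:f0] = CSF
        col[margin:H - margin, f0:f1] = FAT
        if k == 0 or k == S - 1:              # lateral slices: no cord/CSF
            col[(col == CORD) | (col == CSF)] = MUSCLE
    return labels, body_masks


def _ellipsoid_in_parent(parent: np.ndarray, target_fraction: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Ellipsoid clipped to ``parent`` covering ~``target_fraction`` of it.

    The ellipsoid is centred on the parent's bounding-box centre with
    semi-axes proportional to the half-extents; the proportionality scale is
    found by bisection so the *measured* covered fraction matches the target.
    """
    n_parent = int(parent.sum())
    if n_parent == 0:
        raise ValueError("empty parent structure")
    if target_fraction >= 0.995:
        return parent.copy(), 1.0
    idx = np.argwhere(parent)
    lo_c, hi_c = idx.min(axis=0), idx.max(axis=0)
    centre = (lo_c + hi_c) / 2.0
    half = np.maximum((hi_c - lo_c) / 2.0, 0.5)
    grid = np.indices(parent.shape, dtype=np.float64)
    # squared normalized distance from the centre
    d2 = sum(((grid[a] - centre[a]) / half[a]) ** 2 for a in range(3))

    def covered(t: float) -> np.ndarray:
        return parent & (d2 <= t * t)

    lo, hi = 1e-3, 3.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        frac = covered(mid).sum() / n_parent
        if frac < target_fraction:
            lo = mid
        else:
            hi = mid
    mask = covered(hi)
    if not mask.any():                        # guarantee a non-empty lesion
        seed_vox = tuple(np.round(centre).astype(int))
        mask = np.zeros_like(parent)
        mask[seed_vox] = parent[seed_vox]
        if not mask.any():
            mask[tuple(idx[rng.integers(len(idx))])] = True
    return mask, float(mask.sum() / n_parent)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def make_phantom(seed: int, shape: tuple[int, int, int] = (10, 64, 64),
                 n_vertebrae: int = 5,
                 pathology_spec: list[tuple[str, float]] | None = None,
                 spacing: tuple[float, float, float] = (3.0, 1.0, 1.0),
                 tissue_params: dict[int, TissueParams] | None = None,
                 ) -> PhantomScene:
    """Build a deterministic multi-contrast spine phantom scene.

    Parameters
    ----------
    seed
        Seeds all geometry jitter and lesion placement; identical seed and
        arguments reproduce the scene bit-exactly.
    shape
        ``(n_sagittal_slices, rows, cols)`` voxel dimensions.
    n_vertebrae
        Number of stacked vertebral bodies; five mirrors a typical field of
        interest spanning five segments.
    pathology_spec
        List of ``(kind, severity)``. Severity semantics per kind:
        extent fraction of the vertebral body for ``bone_marrow_abnormality``
        and ``spondylodiscitis_expansion``; 1 (acute) or 2 (chronic) for
        ``vertebral_fracture``; subtype 1/2/3 for
        ``paravertebral_abnormality``; ignored for the binary kinds.
    """
    pathology_spec = list(pathology_spec or [])
    tissues = dict(tissue_params or DEFAULT_TISSUES)
    rng = np.random.default_rng(seed)
    labels, body_masks = _build_labels(tuple(shape), n_vertebrae, rng)

    annotations: list[PathologyAnnotation] = []
    for kind, severity in pathology_spec:
        if kind not in PATHOLOGY_KINDS:
            raise ValueError(f"unknown pathology kind {kind!r}")
        v = int(rng.integers(n_vertebrae))
        body = body_masks[v]
        if kind == "bone_marrow_abnormality":
            if not 0 < severity <= 1:
                raise ValueError("bone marrow severity is an extent fraction in (0, 1]")
            mask, extent = _ellipsoid_in_parent(body, float(severity), rng)
            ann = PathologyAnnotation(kind, mask, extent, edema=True,
                                      gt_grade=_extent_grade_bone_marrow(extent),
                                      vertebra_index=v)
        elif kind == "spondylodiscitis_expansion":
            if not 0 < severity <= 1:
                raise ValueError("spondylodiscitis severity is an extent fraction in (0, 1]")
            mask, extent = _ellipsoid_in_parent(body, float(severity), rng)
            ann = PathologyAnnotation(kind, mask, extent, edema=True,
                                      gt_grade=_extent_grade_spondylodiscitis(extent),
                                      vertebra_index=v)
        elif kind == "modic_type1":
            # small edema focus at an endplate (top rows of the body)
            endplate = body.copy()
            rows = np.where(endplate.any(axis=(0, 2)))[0]
            endplate[:, rows[len(rows) // 3]:, :] = False
            mask, _ = _ellipsoid_in_parent(endplate, 0.8, rng)
            extent = float(mask.sum() / body.sum())
            ann = PathologyAnnotation(kind, mask, extent, edema=True, gt_grade=1,
                                      vertebra_index=v)
        elif kind == "vertebral_fracture":
            if int(severity) not in (1, 2):
                raise ValueError("fracture severity must be 1 (acute) or 2 (chronic)")
            band = body.copy()
            rows = np.where(band.any(axis=(0, 2)))[0]
            mid = rows[len(rows) // 2]
            band[:, :max(rows[0], mid - 1), :] = False
            band[:, mid + 2:, :] = False
            acute = int(severity) == 1
            extent = float(band.sum() / body.sum())
            ann = PathologyAnnotation(kind, band, extent, edema=acute,
                                      gt_grade=1 if acute else 2, vertebra_index=v)
        elif kind == "cord_lesion":
            cord = labels == CORD
            if not cord.any():
                raise ValueError("phantom has no cord voxels for a cord lesion")
            mask, _ = _ellipsoid_in_parent(cord, 0.1, rng)
            ann = PathologyAnnotation(kind, mask, 0.0, edema=True, gt_grade=1)
        elif kind == "paravertebral_abnormality":
            subtype = int(severity)
            if subtype not in (1, 2, 3):
                raise ValueError("paravertebral severity must be subtype 1, 2 or 3")
            soft = (labels == FAT) | (labels == MUSCLE)
            mask, _ = _ellipsoid_in_parent(soft, 0.15, rng)
            ann = PathologyAnnotation(kind, mask, 0.0, edema=(subtype == 1),
                                      gt_grade=subtype, subtype=subtype)
        annotations.append(ann)

    return PhantomScene(labels=labels, tissue_params=tissues,
                        pathologies=annotations, spacing=tuple(spacing),
                        seed=int(seed), n_vertebrae=n_vertebrae,
                        vertebra_masks=body_masks)


def compartment_maps(scene: PhantomScene) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (fat, fluid, base) maps after applying lesion effects."""
    n_labels = max(scene.tissue_params) + 1
    lut = np.zeros((n_labels, 3))
    for lab, tp in scene.tissue_params.items():
        lut[lab] = (tp.fat_fraction, tp.fluid_fraction, tp.base_signal)
    fat = lut[scene.labels, 0]
    fluid = lut[scene.labels, 1]
    base = lut[scene.labels, 2]
    for ann in scene.pathologies:
        m = ann.mask
        if ann.edema:
            fluid[m] = fluid[m] + 0.6 * (1 - fluid[m])
            fat[m] = fat[m] * 0.3
        elif ann.kind == "vertebral_fracture":      # chronic: fatty conversion
            fat[m] = fat[m] + 0.5 * (1 - fat[m])
            fluid[m] = fluid[m] * 0.5
        elif ann.subtype == 2:                      # hematoma: fat-like, T1-bright
            fat[m] = fat[m] + 0.4 * (1 - fat[m])
        elif ann.subtype == 3:                      # other: unspecific signal
            base[m] = base[m] + 0.2
    return fat, fluid, base


def render_contrast(scene: PhantomScene, contrast: str, noise_sd: float = 0.0,
                    seed: int = 0) -> ContrastVolume:
    """Render one MR contrast of a phantom scene.

    The per-voxel signal is ``w_fat*fat + w_fluid*fluid + w_base*base`` with
    the contrast-specific weights in :data:`CONTRAST_WEIGHTS`; for T2FS the
    fat weight is zero. Additive Gaussian noise with standard deviation
    ``noise_sd``, deterministic given ``seed``.
    """
    if contrast not in CONTRAST_WEIGHTS:
        raise ValueError(f"unknown contrast {contrast!r}; "
                         f"expected one of {tuple(CONTRAST_WEIGHTS)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    wf, wl, wb = CONTRAST_WEIGHTS[contrast]
    fat, fluid, base = compartment_maps(scene)
    signal = wf * fat + wl * fluid + wb * base
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return ContrastVolume(data=signal, spacing=scene.spacing, contrast=contrast,
                          slice_axis=0)


MAX_MISALIGN_ROTATION_DEG = 15.0
MAX_MISALIGN_TRANSLATION_MM = 20.0


def misalign(vol: ContrastVolume, rotation_deg: float | None = None,
             translation_mm: tuple[float, float] | None = None,
             seed: int = 0) -> tuple[ContrastVolume, RigidTransform2D]:
    """Apply a known in-plane rigid misalignment; returns the exact transform.

    When rotation or translation is ``None`` it is drawn uniformly within the
    allowed range from ``seed``, so registration tests can sample random but
    recoverable misalignments.
    """
    rng = np.random.default_rng(seed)
    if rotation_deg is None:
        rotation_deg = float(rng.uniform(-10, 10))
    if translation_mm is None:
        translation_mm = tuple(rng.uniform(-8, 8, size=2))
    if abs(rotation_deg) > MAX_MISALIGN_ROTATION_DEG:
        raise ValueError(f"|rotation| must be <= {MAX_MISALIGN_ROTATION_DEG} deg")
    if max(abs(translation_mm[0]), abs(translation_mm[1])) > MAX_MISALIGN_TRANSLATION_MM:
        raise ValueError(f"|translation| must be <= {MAX_MISALIGN_TRANSLATION_MM} mm")
    transform = RigidTransform2D(float(rotation_deg),
                                 (float(translation_mm[0]), float(translation_mm[1])),
                                 fixed=None, moving=vol.contrast)
    moved = apply_rigid_inplane(vol.slices(), vol.inplane_spacing, transform)
    out = vol.with_data(np.moveaxis(moved, 0, vol.slice_axis))
    return out, transform


def grade_from_scene(scene: PhantomScene) -> list[tuple[str, int]]:
    """Ground-truth grade for each of the six pathology kinds.

    Extent-graded kinds map the measured extent fraction through the grade
    boundaries (focal below 10 %, thirds at 1/3 and 2/3); fractures grade 1
    when the edema flag is set (acute) and 2 otherwise (chronic); binary and
    subtype kinds report presence / subtype. Multiple lesions of one kind
    report the maximum grade.
    """
    grades = {kind: 0 for kind in PATHOLOGY_KINDS}
    for ann in scene.pathologies:
        if ann.kind == "bone_marrow_abnormality":
            g = _extent_grade_bone_marrow(ann.extent_fraction)
        elif ann.kind == "spondylodiscitis_expansion":
            g = _extent_grade_spondylodiscitis(ann.extent_fraction)
        elif ann.kind == "vertebral_fracture":
            g = 1 if ann.edema else 2
        elif ann.kind == "paravertebral_abnormality":
            g = ann.subtype or 1
        else:                                   # modic_type1, cord_lesion
            g = 1
        grades[ann.kind] = max(grades[ann.kind], g)
    return [(kind, grades[kind]) for kind in PATHOLOGY_KINDS]


# ---------------------------------------------------------------------------
# simulated reader study
# ---------------------------------------------------------------------------

#: Frequency of each pathology among simulated datasets (per-dataset
#: probability of being present), mirroring a mixed clinical spine cohort.
DEFAULT_PREVALENCE: dict[str, float] = {
    "bone_marrow_abnormality": 61 / 101,
    "spondylodiscitis_expansion": 5 / 101,
    "modic_type1": 28 / 101,
    "vertebral_fracture": 21 / 101,
    "cord_lesion": 15 / 101,
    "paravertebral_abnormality": 25 / 101,
}

#: Kinds whose conspicuity depends on fluid contrast: without a fat-saturated
#: image these are the hard calls, so the two-sequence protocol reads them
#: with a higher misgrade probability.
FLUID_SENSITIVE_KINDS = ("bone_marrow_abnormality", "spondylodiscitis_expansion",
                         "modic_type1", "cord_lesion")

DEFAULT_ERROR_RATES: dict[str, dict[str, float]] = {
    "two_sequence": {kind: (0.30 if kind in FLUID_SENSITIVE_KINDS else 0.15)
                     for kind in PATHOLOGY_KINDS},
    "synthetic_protocol": {kind: 0.10 for kind in PATHOLOGY_KINDS},
}


def sample_ground_truth(seed: int, n_datasets: int = 101,
                        prevalence: dict[str, float] | None = None) -> pd.DataFrame:
    """Sample a ground-truth grading table for ``n_datasets`` virtual patients.

    Each pathology is present with its prevalence probability; present
    pathologies draw a grade uniformly from the legal non-zero grades.
    Returns one row per (dataset, pathology kind).
    """
    prevalence = dict(prevalence or DEFAULT_PREVALENCE)
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_datasets):
        for kind in PATHOLOGY_KINDS:
            p = prevalence.get(kind, 0.0)
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {kind} outside [0, 1]")
            if rng.random() < p:
                lo, hi = GRADE_RANGES[kind]
                grade = int(rng.integers(max(lo, 1), hi + 1))
            else:
                grade = 0
            rows.append({"dataset_id": d, "pathology": kind, "gt_grade": grade})
    return pd.DataFrame(rows)


def _adjacent_misgrade(grade: int, kind: str, rng: np.random.Generator) -> int:
    lo, hi = GRADE_RANGES[kind]
    options = [g for g in (grade - 1, grade + 1) if lo <= g <= hi]
    return int(options[rng.integers(len(options))])


def simulate_readers(gt: pd.DataFrame, protocol: str,
                     error_model: dict[str, float] | float | None = None,
                     seed: int = 0, n_readers: int = 2,
                     reader_ids: tuple = (1, 2)) -> pd.DataFrame:
    """Simulate reader gradings under one reading protocol.

    With per-kind probability ``error_model[kind]`` a reader misgrades to an
    adjacent grade (clipped to the legal range); otherwise the ground truth is
    reported. Deterministic given ``seed``.
    """
    if protocol not in ("two_sequence", "synthetic_protocol"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if error_model is None:
        errors = DEFAULT_ERROR_RATES[protocol]
    elif isinstance(error_model, (int, float)):
        errors = {kind: float(error_model) for kind in PATHOLOGY_KINDS}
    else:
        errors = {kind: float(error_model.get(kind, 0.0)) for kind in PATHOLOGY_KINDS}
    for kind, p in errors.items():
        if not 0 <= p <= 1:
            raise ValueError(f"misgrade probability for {kind} outside [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_readers):
        rid = reader_ids[r] if r < len(reader_ids) else r + 1
        for rec in gt.itertuples(index=False):
            g = int(rec.gt_grade)
            if rng.random() < errors[rec.pathology]:
                g = _adjacent_misgrade(g, rec.pathology, rng)
            rows.append({"dataset_id": rec.dataset_id, "reader_id": rid,
                         "protocol": protocol, "pathology": rec.pathology,
                         "grade": g, "gt_grade": int(rec.gt_grade)})
    return pd.DataFrame(rows)
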