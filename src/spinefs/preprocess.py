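"""Preprocessing chain: resample, co-register, cap, scale, slice.

Volumes go through four steps before they touch the GAN:

1. linear in-plane resampling to 1 x 1 mm;
2. rigid in-plane co-registration of the moving contrasts onto the fixed
   T2-w volume (mean-squared-difference similarity, coarse grid search plus
   Powell refinement);
3. intensity capping at the 1st and 99th percentile followed by an affine
   map of [p1, p99] onto [-1, +1];
4. extraction of aligned sagittal slice pairs as the training unit.

Percentiles use the linear-interpolation order-statistic convention and are
computed per volume. Resampling uses voxel-centre alignment with a half-open
world extent, so an (H, W) plane at spacing s becomes round(H*s) x round(W*s)
voxels at 1 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .rigid import RigidTransform2D, apply_rigid_inplane
from .volumes import ContrastVolume


@dataclass(frozen=True)
class NormalizationRecord:
    """Stored capping percentiles so inference can invert the scaling."""

    p_low: float
    p_high: float
    contrast: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.p_low > self.p_high:
            raise ValueError("p_low must not exceed p_high")

    def to_json(self) -> str:
        return json.dumps({"p_low": self.p_low, "p_high": self.p_high,
                           "contrast": self.contrast, "degenerate": self.degenerate})

    @classmethod
    def from_json(cls, s: str) -> "NormalizationRecord":
        return cls(**json.loads(s))


def resample_inplane(vol: ContrastVolume, target_mm: float = 1.0) -> ContrastVolume:
    """Linearly resample the in-plane axes to ``target_mm`` spacing.

    The slice axis is untouched. Output grid convention: voxel centres with a
    half-open world extent, i.e. ``out_size = round(in_size * spacing /
    target)`` and output centre ``i`` sits at world ``(i + 0.5) * target``.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("volume contains non-finite intensities")
    sr, sc = vol.inplane_spacing
    slices = vol.slices()
    _, H, W = slices.shape
    Ho = max(1, round(H * sr / target_mm))
    Wo = max(1, round(W * sc / target_mm))
    rr = ((np.arange(Ho) + 0.5) * target_mm) / sr - 0.5
    cc = ((np.arange(Wo) + 0.5) * target_mm) / sc - 0.5
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    coords = np.stack([grid_r.ravel(), grid_c.ravel()])
    out = np.empty((slices.shape[0], Ho, Wo))
    for k in range(slices.shape[0]):
        out[k] = ndimage.map_coordinates(slices[k], coords, order=1,
                                         mode="nearest").reshape(Ho, Wo)
    axes = [a for a in range(3) if a != vol.slice_axis]
    spacing = list(vol.spacing)
    spacing[axes[0]] = spacing[axes[1]] = float(target_mm)
    data = np.moveaxis(out, 0, vol.slice_axis)
    return ContrastVolume(data=data, spacing=tuple(spacing), contrast=vol.contrast,
                          slice_axis=vol.slice_axis, meta=dict(vol.meta))


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

def _zscore(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    return (img - img.mean()) / sd


def _mse_objective(params: np.ndarray, moving: np.ndarray, fixed: np.ndarray,
                   spacing: tuple[float, float]) -> float:
    tf = RigidTransform2D(params[0], (params[1], params[2]))
    moved = apply_rigid_inplane(moving[None], spacing, tf)[0]
    return float(np.mean((moved - fixed) ** 2))


def rigid_register(moving: ContrastVolume, fixed: ContrastVolume,
                   max_rotation_deg: float = 15.0, max_translation_mm: float = 20.0,
                   ) -> tuple[RigidTransform2D, ContrastVolume]:
    """Estimate the in-plane rigid transform aligning ``moving`` onto ``fixed``.

    Minimizes the mean squared difference of z-normalized mean sagittal
    slices: a coarse rotation/translation grid search on 2x-downsampled
    images seeds a Powell refinement at full resolution. Returns the
    estimated transform and the moving volume resampled into fixed space.

    The returned transform maps moving-space content onto fixed space, so for
    a volume misaligned by a known transform ``T`` the estimate approximates
    ``T.inverse()``.
    """
    if moving.slices().shape != fixed.slices().shape:
        raise ValueError("moving and fixed volumes must share a shape")
    m2d = moving.slices().mean(axis=0)
    f2d = fixed.slices().mean(axis=0)
    if m2d.std() == 0 or f2d.std() == 0:
        raise ValueError("registration undefined: constant image")
    m2d, f2d = _zscore(m2d), _zscore(f2d)
    spacing = moving.inplane_spacing

    # coarse: 2x-decimated grid search
    m_lo, f_lo = m2d[::2, ::2], f2d[::2, ::2]
    sp_lo = (spacing[0] * 2, spacing[1] * 2)
    rots = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, 3.0)
    shifts = np.arange(-max_translation_mm * 0.6, max_translation_mm * 0.6 + 1e-9, 3.0)
    best, best_val = (0.0, 0.0, 0.0), np.inf
    for r in rots:
        for tr in shifts:
            for tc in shifts:
                val = _mse_objective(np.array([r, tr, tc]), m_lo, f_lo, sp_lo)
                if val < best_val:
                    best, best_val = (r, tr, tc), val

    res = optimize.minimize(
        _mse_objective, x0=np.array(best), args=(m2d, f2d, spacing),
        method="Powell",
        bounds=[(-max_rotation_deg, max_rotation_deg),
                (-max_translation_mm, max_translation_mm),
                (-max_translation_mm, max_translation_mm)],
        options={"xtol": 1e-4, "ftol": 1e-8})
    est = RigidTransform2D(float(res.x[0]), (float(res.x[1]), float(res.x[2])),
                           fixed=fixed.contrast, moving=moving.contrast)
    moved = apply_rigid_inplane(moving.slices(), spacing, est)
    out = moving.with_data(np.moveaxis(moved, 0, moving.slice_axis))
    return est, out


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def cap_and_scale(vol: ContrastVolume) -> tuple[ContrastVolume, NormalizationRecord]:
    """Cap intensities at the 1st/99th percentile and scale to [-1, 1].

    ``p1 -> -1`` and ``p99 -> +1`` affinely, values outside clipped first.
    Degenerate volumes (``p1 == p99``) map to all zeros with a flagged record
    so callers can detect and skip them.
    """
    p1, p99 = np.percentile(vol.data, [1.0, 99.0])
    if p99 <= p1:
        record = NormalizationRecord(float(p1), float(p99), vol.contrast,
                                     degenerate=True)
        return vol.with_data(np.zeros_like(vol.data)), record
    clipped = np.clip(vol.data, p1, p99)
    scaled = (clipped - p1) / (p99 - p1) * 2.0 - 1.0
    record = NormalizationRecord(float(p1), float(p99), vol.contrast)
    return vol.with_data(scaled), record


def invert_scale(vol: ContrastVolume, record: NormalizationRecord) -> ContrastVolume:
    """Map a [-1, 1] volume back to the clipped intensity range of its record."""
    if record.degenerate:
        return vol.with_data(np.full_like(vol.data, record.p_low))
    data = (vol.data + 1.0) / 2.0 * (record.p_high - record.p_low) + record.p_low
    return vol.with_data(data)


# ---------------------------------------------------------------------------
# paired slices
# ---------------------------------------------------------------------------

@dataclass
class PairedSliceDataset:
    """Aligned sagittal (T1, T2) -> T2fs slice pairs in [-1, 1].

    ``inputs`` has shape (N, 2, H, W); ``targets`` has shape (N, 1, H, W) or
    is ``None`` in synthesis-only mode.
    """

    inputs: np.ndarray
    targets: np.ndarray | None
    slice_indices: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        if self.inputs.ndim != 4 or self.inputs.shape[1] != 2:
            raise ValueError("inputs must have shape (N, 2, H, W)")
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=np.float32)
            if self.targets.shape != (self.inputs.shape[0], 1, *self.inputs.shape[2:]):
                raise ValueError("targets must have shape (N, 1, H, W) matching inputs")
        self.slice_indices = np.asarray(self.slice_indices, dtype=np.int64)
        if len(self.slice_indices) != len(self.inputs):
            raise ValueError("one slice index per record required")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def has_targets(self) -> bool:
        return self.targets is not None

    def subset(self, idx) -> "PairedSliceDataset":
        idx = np.asarray(idx)
        return PairedSliceDataset(
            self.inputs[idx],
            None if self.targets is None else self.targets[idx],
            self.slice_indices[idx], dict(self.meta))

    @staticmethod
    def concatenate(datasets: list["PairedSliceDataset"]) -> "PairedSliceDataset":
        if not datasets:
            raise ValueError("no datasets to concatenate")
        has_t = all(d.has_targets for d in datasets)
        return PairedSliceDataset(
            np.concatenate([d.inputs for d in datasets]),
            np.concatenate([d.targets for d in datasets]) if has_t else None,
            np.concatenate([d.slice_indices for d in datasets]))


def extract_sagittal_slices(t1: ContrastVolume, t2: ContrastVolume,
                            t2fs: ContrastVolume | None = None,
                            aligned: bool = True) -> PairedSliceDataset:
    """Split co-registered volumes into per-slice training records.

    All volumes must be identically shaped and already scaled to [-1, 1].
    With ``t2fs=None`` the dataset carries empty targets and is usable for
    synthesis only.
    """
    vols = [t1, t2] + ([t2fs] if t2fs is not None else [])
    shapes = {v.slices().shape for v in vols}
    if len(shapes) > 1:
        raise ValueError(f"volume shapes differ: {sorted(shapes)}")
    if not aligned:
        raise ValueError("volumes must be co-registered before slice extraction")
    for v in vols:
        if v.data.min() < -1.0 - 1e-6 or v.data.max() > 1.0 + 1e-6:
            raise ValueError(f"{v.contrast} volume not scaled to [-1, 1]; "
                             "run cap_and_scale first")
    n = t1.n_slices
    inputs = np.stack([t1.slices(), t2.slices()], axis=1)
    targets = None if t2fs is None else t2fs.slices()[:, None]
    return PairedSliceDataset(inputs=inputs, targets=targets,
                              slice_indices=np.arange(n),
                              meta={"spacing": t1.spacing})


def preprocess_volumes(t1: ContrastVolume, t2: ContrastVolume,
                       t2fs: ContrastVolume | None = None,
                       target_mm: float = 1.0, register: bool = True,
                       ) -> tuple[dict[str, ContrastVolume],
                                  dict[str, NormalizationRecord],
                                  dict[str, RigidTransform2D]]:
    """Full chain: resample -> register (T2-w fixed) -> cap-and-scale.

    Returns the preprocessed volumes, the normalization records and the
    estimated transforms (identity entries omitted).
    """
    vols = {"T1": resample_inplane(t1, target_mm), "T2": resample_inplane(t2, target_mm)}
    if t2fs is not None:
        vols["T2FS"] = resample_inplane(t2fs, target_mm)
    transforms: dict[str, RigidTransform2D] = {}
    if register:
        for key in [k for k in vols if k != "T2"]:
            tf, moved = rigid_register(vols[key], vols["T2"])
            vols[key] = moved
            transforms[key] = tf
    records: dict[str, NormalizationRecord] = {}
    for key in list(vols):
        vols[key], records[key] = cap_and_scale(vols[key])
    return vols, records, transforms


def save_normalization_records(records: dict[str, NormalizationRecord],
                               path: str | Path) -> None:
    payload = {k: json.loads(r.to_json()) for k, r in records.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_normalization_records(path: str | Path) -> dict[str, NormalizationRecord]:
    payload = json.loads(Path(path).read_text())
    return {k: NormalizationRecord(**v) for k, v in payload.items()}
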