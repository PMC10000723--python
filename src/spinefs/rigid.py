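"""In-plane rigid transforms shared by the phantom simulator and registration.

A transform ``T = (theta, t)`` acts on an image by rotating it ``theta``
degrees counter-clockwise about the in-plane centre (in millimetre
coordinates) and then translating it by ``t`` millimetres:
``(T f)(x) = f(R(-theta) (x - t))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def _rot(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid transform: rotation (degrees) then translation (mm).

    ``fixed``/``moving`` record which contrasts the transform maps between
    when it comes out of registration; they do not affect the geometry.
    """

    rotation_deg: float
    translation_mm: tuple[float, float]
    fixed: str | None = None
    moving: str | None = None

    def inverse(self) -> "RigidTransform2D":
        t = _rot(-self.rotation_deg) @ np.asarray(self.translation_mm)
        return RigidTransform2D(-self.rotation_deg, (-t[0], -t[1]),
                                fixed=self.moving, moving=self.fixed)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        t = np.asarray(self.translation_mm) + _rot(self.rotation_deg) @ np.asarray(
            other.translation_mm)
        return RigidTransform2D(self.rotation_deg + other.rotation_deg, (t[0], t[1]))

    def as_params(self) -> tuple[float, float, float]:
        return (self.rotation_deg, self.translation_mm[0], self.translation_mm[1])


def apply_rigid_inplane(slices: np.ndarray, spacing: tuple[float, float],
                        transform: RigidTransform2D, order: int = 1,
                        cval: float = 0.0) -> np.ndarray:
    """Apply an in-plane rigid transform to every slice of ``(N, H, W)`` data.

    Rotation is about each slice's centre; translation is in millimetres with
    the given in-plane ``spacing``. Linear interpolation by default, constant
    padding outside the field of view.
    """
    slices = np.asarray(slices, dtype=np.float64)
    if slices.ndim != 3:
        raise ValueError("expected (n_slices, H, W) data")
    sr, sc = spacing
    D = np.diag([sr, sc])
    Dinv = np.diag([1.0 / sr, 1.0 / sc])
    Rinv = _rot(-transform.rotation_deg)
    centre = (np.array(slices.shape[1:]) - 1) / 2.0
    t = np.asarray(transform.translation_mm)
    # out[o] = in[M @ o + off] with o in index coordinates
    M = Dinv @ Rinv @ D
    off = centre - M @ centre - Dinv @ (Rinv @ t)
    out = np.empty_like(slices)
    for k in range(slices.shape[0]):
        out[k] = ndimage.affine_transform(slices[k], M, offset=off, order=order,
                                          mode="constant", cval=cval)
    return out
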