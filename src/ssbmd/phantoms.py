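"""Digital phantoms for single-energy radiographic bone densitometry.

The object being imaged is described by a two-map morphological model: a
posteroanterior *total thickness* map (cm of tissue along each ray) and an
*alloy* map giving the proportion of soft tissue along the same ray.  Bone
thickness is therefore ``thickness * (1 - alloy)``, and, multiplied by the
assumed volumetric density of bone, becomes areal bone mineral density
(aBMD, g/cm^2).

This module generates ground-truth instances of that model:

* uniform slabs (physics test objects),
* calibration step wedges (banded thickness/alloy steps), and
* anatomically plausible forearms with a radius and an ulna, a known radial
  styloid landmark, and seedable morphological variation.

Coordinate conventions (used throughout the package): grids are row-major
with 0-based indices, rectangles are half-open ``[r0, r1) x [c0, c1)``, the
image long axis runs along columns, and *distal* means smaller column
index.  Laterality is handled by mirroring across the long axis (row flip),
so the distal direction is the same for left and right arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

#: Default field of view 24 cm x 12 cm at 0.05 cm pixel pitch -> 240 x 480
#: pixels (rows x cols; the long 24 cm axis runs along columns).
DEFAULT_SHAPE: tuple[int, int] = (240, 480)
DEFAULT_PIXEL_PITCH: float = 0.05

#: Projected bone thickness (cm) above which a pixel counts as bone when a
#: binary bone mask is derived from the maps.  Shared with the ROI module so
#: ground-truth landmarks and detected landmarks use the same convention.
BONE_MASK_THRESHOLD_CM: float = 0.05


class PhantomParameterError(ValueError):
    """A phantom parameter lies outside its documented plausible range."""


@dataclass
class MorphologicalModel:
    """Paired thickness/alloy maps describing the imaged object.

    Attributes
    ----------
    thickness:
        2-D posteroanterior total thickness, cm per pixel, >= 0.
    alloy:
        2-D soft-tissue proportion in [0, 1]; background pixels
        (thickness == 0) carry alloy == 1 by convention.
    pixel_pitch:
        Detector pixel pitch in cm.
    laterality:
        ``"left"`` or ``"right"``.
    """

    thickness: np.ndarray
    alloy: np.ndarray
    pixel_pitch: float
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.alloy = np.asarray(self.alloy, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.thickness.ndim != 2 or self.thickness.shape != self.alloy.shape:
            raise ValueError("thickness and alloy must be 2-D grids of equal shape")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        if np.any(self.thickness < 0):
            raise ValueError("thickness must be non-negative everywhere")
        if np.any((self.alloy < 0) | (self.alloy > 1)):
            raise ValueError("alloy must lie in [0, 1] everywhere")
        if np.any(self.alloy[self.thickness == 0] != 1.0):
            raise ValueError("background (thickness == 0) pixels must carry alloy == 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.thickness.shape

    @property
    def fov_cm(self) -> tuple[float, float]:
        """(rows, cols) extent in cm: grid dimensions x pixel pitch."""
        return (self.shape[0] * self.pixel_pitch, self.shape[1] * self.pixel_pitch)

    def bone_thickness(self) -> np.ndarray:
        """Projected bone thickness map, cm: thickness * (1 - alloy)."""
        return self.thickness * (1.0 - self.alloy)

    def bone_mask(self, threshold_cm: float = BONE_MASK_THRESHOLD_CM) -> np.ndarray:
        return self.bone_thickness() > threshold_cm

    def mirrored(self) -> "MorphologicalModel":
        """Mirror across the long axis, flipping laterality."""
        other = "left" if self.laterality == "right" else "right"
        return MorphologicalModel(
            thickness=self.thickness[::-1].copy(),
            alloy=self.alloy[::-1].copy(),
            pixel_pitch=self.pixel_pitch,
            laterality=other,
        )


@dataclass
class ForearmGeometry:
    """Ground-truth landmarks of a generated forearm phantom.

    ``styloid`` is the (row, col) pixel of the radial styloid tip, defined as
    the most distal (smallest column) pixel of the radius bone mask, ties
    broken toward the smaller row index.  ``arm_length_cm`` is the
    styloid-to-olecranon distance; 29 cm is the conventional default when it
    has not been measured.
    """

    styloid: tuple[int, int] | None
    radius_axis: np.ndarray | None = None
    ulna_axis: np.ndarray | None = None
    arm_length_cm: float = 29.0

    def __post_init__(self) -> None:
        if self.arm_length_cm <= 0:
            raise ValueError("arm_length_cm must be positive")


def make_slab_phantom(
    thickness_cm: float,
    alloy: float,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> MorphologicalModel:
    """Uniform slab covering the whole field.

    A zero-thickness slab is an empty field and carries alloy 1 everywhere
    regardless of the requested alloy (background convention).
    """
    if thickness_cm < 0:
        raise PhantomParameterError("thickness_cm must be >= 0")
    if not 0.0 <= alloy <= 1.0:
        raise PhantomParameterError("alloy must lie in [0, 1]")
    if shape[0] <= 0 or shape[1] <= 0:
        raise PhantomParameterError("shape must be positive")
    t = np.full(shape, float(thickness_cm))
    a = np.full(shape, float(alloy) if thickness_cm > 0 else 1.0)
    return MorphologicalModel(t, a, pixel_pitch)


def make_step_wedge(
    steps: Sequence[tuple[float, float]],
    shape: tuple[int, int] = (64, 256),
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
) -> MorphologicalModel:
    """Calibration step wedge: vertical bands, one per (thickness, alloy) step,
    laid out left to right in list order."""
    if len(steps) < 2:
        raise PhantomParameterError("a step wedge needs at least 2 steps")
    for t_cm, a in steps:
        if t_cm < 0:
            raise PhantomParameterError("step thickness must be >= 0")
        if not 0.0 <= a <= 1.0:
            raise PhantomParameterError("step alloy must lie in [0, 1]")
    rows, cols = shape
    t = np.zeros(shape)
    a_map = np.ones(shape)
    edges = np.linspace(0, cols, len(steps) + 1).round().astype(int)
    for (t_cm, a), c0, c1 in zip(steps, edges[:-1], edges[1:]):
        t[:, c0:c1] = t_cm
        a_map[:, c0:c1] = a if t_cm > 0 else 1.0
    return MorphologicalModel(t, a_map, pixel_pitch)


def wedge_bands(model: MorphologicalModel) -> list[tuple[int, int]]:
    """Column ranges [c0, c1) of the constant bands of a step-wedge model."""
    t_col = model.thickness[0]
    a_col = model.alloy[0]
    change = np.flatnonzero((np.diff(t_col) != 0) | (np.diff(a_col) != 0)) + 1
    edges = np.concatenate([[0], change, [model.shape[1]]])
    return list(zip(edges[:-1], edges[1:]))


@dataclass
class ForearmParams:
    """Generator parameters for anatomically plausible forearm phantoms.

    Defaults emulate an adult forearm imaged PA over a 24 cm x 12 cm field:
    a smooth elliptical soft-tissue dome whose summit thickness ramps from
    ~4.6 cm near the wrist to ~7.6 cm proximally, and two elongated bones
    (radius, ulna) whose projected thickness follows elliptical chords of the
    bone cross-section.  Per-seed jitters spread the region-averaged bone
    thickness over the plausible adult range (roughly 0.4-2.2 cm at the
    ultra-distal site).
    """

    shape: tuple[int, int] = DEFAULT_SHAPE
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    arm_length_cm: float = 29.0
    laterality: str = "right"
    styloid_offset_cm: float = 2.2
    radius_halfwidth_cm: float = 0.8
    ulna_halfwidth_cm: float = 0.6
    bone_fraction_scale: float = 0.8
    thickness_distal_cm: float = 4.6
    thickness_proximal_cm: float = 7.6
    soft_halfwidth_distal_cm: float = 3.4
    soft_halfwidth_proximal_cm: float = 4.6
    bone_jitter: tuple[float, float] = (0.62, 1.42)
    thickness_jitter: tuple[float, float] = (0.92, 1.08)
    smooth_sigma_cm: float = 0.18

    def validate(self) -> None:
        if not (2.0 <= self.thickness_distal_cm <= 10.0 and 2.0 <= self.thickness_proximal_cm <= 10.0):
            raise PhantomParameterError("summit thicknesses must lie in [2, 10] cm")
        if self.thickness_proximal_cm * max(self.thickness_jitter) > 10.0:
            raise PhantomParameterError("thickness jitter would exceed the 10 cm plausible range")
        for name in ("radius_halfwidth_cm", "ulna_halfwidth_cm"):
            v = getattr(self, name)
            if not 0.3 <= v <= 2.0:
                raise PhantomParameterError(f"{name} must lie in [0.3, 2.0] cm")
        if not 0.0 <= self.bone_fraction_scale <= 1.0:
            raise PhantomParameterError("bone_fraction_scale must lie in [0, 1]")
        if self.arm_length_cm <= 0:
            raise PhantomParameterError("arm_length_cm must be positive")
        if self.laterality not in ("left", "right"):
            raise PhantomParameterError("laterality must be 'left' or 'right'")
        half_fov = self.shape[0] * self.pixel_pitch / 2.0
        if self.soft_halfwidth_proximal_cm >= half_fov:
            raise PhantomParameterError("soft-tissue halfwidth exceeds the field of view")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def make_forearm_phantom(
    params: ForearmParams | None = None,
    seed: int = 0,
) -> tuple[MorphologicalModel, ForearmGeometry]:
    """Generate a seeded forearm phantom and its ground-truth geometry.

    The output is a pure function of ``(params, seed)``.  The styloid
    landmark is the most distal pixel of the radius bone mask (ties toward
    the smaller row).  With ``bone_fraction_scale == 0`` the phantom carries
    no bone (alloy == 1 everywhere) and the styloid is ``None``.
    """
    params = params or ForearmParams()
    params.validate()
    rng = np.random.default_rng(seed)
    rows, cols = params.shape
    p = params.pixel_pitch

    tmul = rng.uniform(*params.thickness_jitter)
    bmul = rng.uniform(*params.bone_jitter)
    rmul = rng.uniform(0.92, 1.08)
    r0_cm = rows * p / 2.0 + rng.uniform(-0.4, 0.4)
    x_sty = params.styloid_offset_cm + rng.uniform(0.0, 0.6)

    r_cm = (np.arange(rows) + 0.5)[:, None] * p
    x_cm = (np.arange(cols) + 0.5)[None, :] * p

    # Soft-tissue dome: elliptical chord across the arm, summit ramping
    # distal -> proximal.
    u = _smoothstep((x_cm - 2.0) / 14.0)
    halfwidth = params.soft_halfwidth_distal_cm + (
        params.soft_halfwidth_proximal_cm - params.soft_halfwidth_distal_cm
    ) * u
    summit = (
        params.thickness_distal_cm
        + (params.thickness_proximal_cm - params.thickness_distal_cm) * u
    ) * tmul
    d_norm = (r_cm - r0_cm) / halfwidth
    thickness = summit * np.sqrt(np.clip(1.0 - d_norm**2, 0.0, None))

    # Bones: projected thickness = elliptical chord 2*s*sqrt(R^2 - d^2) of a
    # rounded capsule along the arm axis, with a mild distal flare on the
    # radius (metaphysis).
    s_eff = float(np.clip(params.bone_fraction_scale * bmul, 0.0, 1.0))

    def bone_map(tip_x: float, center_row_cm: np.ndarray, halfwidth_bone: np.ndarray) -> np.ndarray:
        u_long = np.maximum(0.0, tip_x - x_cm)
        d2 = (r_cm - center_row_cm) ** 2 + u_long**2
        return 2.0 * s_eff * np.sqrt(np.clip(halfwidth_bone**2 - d2, 0.0, None))

    radius_row = r0_cm - 0.38 * halfwidth
    radius_R = params.radius_halfwidth_cm * rmul * (
        1.0 + 0.25 * np.exp(-np.maximum(0.0, x_cm - x_sty) / 2.5)
    )
    ulna_row = r0_cm + 0.38 * halfwidth
    ulna_R = params.ulna_halfwidth_cm * rmul * (
        1.0 + 0.12 * np.exp(-np.maximum(0.0, x_cm - x_sty - 1.3) / 2.5)
    )
    bone = bone_map(x_sty, radius_row, radius_R) + bone_map(x_sty + 1.3, ulna_row, ulna_R)
    bone = np.minimum(bone, 0.92 * thickness)

    # Smooth both maps for realistic edge falloff, then re-impose physical
    # constraints.
    sigma_px = params.smooth_sigma_cm / p
    thickness = gaussian_filter(thickness, sigma_px, mode="nearest")
    bone = gaussian_filter(bone, sigma_px, mode="nearest")
    thickness = np.clip(thickness, 0.0, None)
    bone = np.clip(np.minimum(bone, 0.92 * thickness), 0.0, None)

    alloy = np.ones_like(thickness)
    fg = thickness > 1e-9
    alloy[fg] = 1.0 - bone[fg] / thickness[fg]
    alloy = np.clip(alloy, 0.0, 1.0)
    thickness[~fg] = 0.0

    model = MorphologicalModel(thickness, alloy, p, laterality="right")

    radius_cols = np.flatnonzero(x_cm[0] >= x_sty)
    radius_axis = np.column_stack([radius_row[0, radius_cols] / p - 0.5, radius_cols])
    ulna_cols = np.flatnonzero(x_cm[0] >= x_sty + 1.3)
    ulna_axis = np.column_stack([ulna_row[0, ulna_cols] / p - 0.5, ulna_cols])

    styloid = _most_distal_pixel(model.bone_mask())
    geometry = ForearmGeometry(
        styloid=styloid,
        radius_axis=radius_axis,
        ulna_axis=ulna_axis,
        arm_length_cm=params.arm_length_cm,
    )

    if params.laterality == "left":
        model = model.mirrored()
        if styloid is not None:
            geometry = replace(geometry, styloid=(rows - 1 - styloid[0], styloid[1]))
        if geometry.radius_axis is not None:
            geometry.radius_axis = geometry.radius_axis * np.array([-1.0, 1.0]) + np.array(
                [rows - 1.0, 0.0]
            )
        if geometry.ulna_axis is not None:
            geometry.ulna_axis = geometry.ulna_axis * np.array([-1.0, 1.0]) + np.array(
                [rows - 1.0, 0.0]
            )
    return model, geometry


def _most_distal_pixel(mask: np.ndarray) -> tuple[int, int] | None:
    """Most distal (smallest column) true pixel; ties -> smallest row."""
    if not mask.any():
        return None
    rr, cc = np.nonzero(mask)
    c_min = cc.min()
    r_min = rr[cc == c_min].min()
    return (int(r_min), int(c_min))


# ---------------------------------------------------------------------------
# HDF5 container


def save_model(
    path: str,
    model: MorphologicalModel,
    geometry: ForearmGeometry | None = None,
) -> None:
    """Write a MorphologicalModel (and optional geometry) to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("thickness", data=model.thickness)
        f.create_dataset("alloy", data=model.alloy)
        f.attrs["pixel_pitch_cm"] = model.pixel_pitch
        f.attrs["laterality"] = model.laterality
        if geometry is not None:
            f.attrs["arm_length_cm"] = geometry.arm_length_cm
            if geometry.styloid is not None:
                f.attrs["styloid_rc"] = np.asarray(geometry.styloid, dtype=int)


def load_model(path: str) -> tuple[MorphologicalModel, ForearmGeometry | None]:
    with h5py.File(path, "r") as f:
        model = MorphologicalModel(
            thickness=f["thickness"][...],
            alloy=f["alloy"][...],
            pixel_pitch=float(f.attrs["pixel_pitch_cm"]),
            laterality=str(f.attrs["laterality"]),
        )
        geometry = None
        if "arm_length_cm" in f.attrs:
            styloid = None
            if "styloid_rc" in f.attrs:
                rc = np.asarray(f.attrs["styloid_rc"], dtype=int)
                styloid = (int(rc[0]), int(rc[1]))
            geometry = ForearmGeometry(
                styloid=styloid, arm_length_cm=float(f.attrs["arm_length_cm"])
            )
    return model, geometry
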