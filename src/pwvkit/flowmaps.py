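"""Flow-curve extraction from through-plane phase-contrast velocity maps.

A phase-contrast acquisition encodes through-plane blood velocity in image
phase; integrating velocity over a vessel region of interest gives the
volumetric flow per time frame:

    flow(t) = sum_{pixels in ROI} v(t, pixel) * pixel_area

with velocity in cm/s and pixel area in mm^2, so ml/s = cm/s * mm^2 / 100.

Vessel segmentation is not performed here — ROI masks are supplied inputs
(static by default, optionally one per frame).  The extraction never flips
the velocity sign; the caller states the through-plane sign convention via
``flip_sign`` when positive phase encodes flow away from the heart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import FlowCurve
from .errors import InputError

__all__ = [
    "VelocitySeries",
    "RoiMask",
    "extract_flow_curve",
    "load_velocity_series",
    "load_roi_mask",
]

_CM_S_MM2_TO_ML_S = 1e-2  # 1 cm/s * 1 mm^2 = 0.01 cm^3/s = 0.01 ml/s


@dataclass(frozen=True)
class VelocitySeries:
    """An ordered series of 2D through-plane velocity maps.

    frames
        Array of shape (T, H, W), velocities in cm/s.
    pixel_spacing
        In-plane pixel size (row_mm, col_mm).
    frame_times
        Frame mid-times in ms, strictly increasing, within the cycle.
    venc
        Velocity-encoding limit in cm/s; all |velocities| must be <= venc.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_times: np.ndarray
    venc: float

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)
        if frames.ndim != 3:
            raise InputError(f"frames must be (T, H, W), got shape {frames.shape}")
        if times.ndim != 1 or times.size != frames.shape[0]:
            raise InputError("frame_times must match the number of frames")
        if np.any(np.diff(times) <= 0):
            raise InputError("frame_times must be strictly increasing")
        if self.venc <= 0:
            raise InputError(f"venc must be > 0, got {self.venc}")
        if np.max(np.abs(frames)) > self.venc * (1 + 1e-9):
            raise InputError("velocities exceed the stated venc (aliasing?)")
        if min(self.pixel_spacing) <= 0:
            raise InputError(f"invalid pixel spacing {self.pixel_spacing}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])

    @property
    def cycle_ms(self) -> float:
        """Cycle length inferred from the uniform frame grid."""
        spacing = np.median(np.diff(self.frame_times))
        return float(self.n_frames * spacing)


@dataclass(frozen=True)
class RoiMask:
    """Binary vessel mask, static (H, W) or per-frame (T, H, W)."""

    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask).astype(bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim not in (2, 3):
            raise InputError(f"mask must be 2D or 3D, got shape {mask.shape}")
        axis = tuple(range(1, mask.ndim)) if mask.ndim == 3 else None
        counts = mask.sum(axis=axis)
        if np.any(np.asarray(counts) == 0):
            raise InputError("every mask frame needs at least one foreground pixel")

    def frame(self, t: int) -> np.ndarray:
        return self.mask if self.mask.ndim == 2 else self.mask[t]


def extract_flow_curve(
    series: VelocitySeries,
    mask: RoiMask,
    flip_sign: bool = False,
) -> FlowCurve:
    """Integrate through-plane velocity over the ROI into a flow curve.

    Returns flow in ml/s per frame: ``sum(v) * pixel_area / 100`` with v in
    cm/s and pixel area in mm^2 (1 cm/s x 1 mm^2 = 0.01 ml/s).
    """
    shape = series.frames.shape[1:]
    mask_shape = mask.mask.shape[-2:]
    if mask_shape != shape:
        raise InputError(
            f"mask shape {mask_shape} does not match frame shape {shape}"
        )
    if mask.mask.ndim == 3 and mask.mask.shape[0] != series.n_frames:
        raise InputError("per-frame mask must have one frame per velocity map")

    flows = np.empty(series.n_frames)
    for t in range(series.n_frames):
        flows[t] = series.frames[t][mask.frame(t)].sum()
    flows *= series.pixel_area_mm2 * _CM_S_MM2_TO_ML_S
    if flip_sign:
        flows = -flows
    return FlowCurve(times=series.frame_times.copy(), flows=flows,
                     cycle_ms=series.cycle_ms)


def load_velocity_series(
    path,
    venc: float,
    frame_interval_ms: float | None = None,
    frame_times=None,
) -> VelocitySeries:
    """Read a velocity series from a NIfTI volume (frames stacked on the
    last axis, values in cm/s).

    Exactly one of ``frame_interval_ms`` / ``frame_times`` must be given;
    the NIfTI header supplies the in-plane pixel spacing.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    data = np.squeeze(data)
    if data.ndim != 3:
        raise InputError(f"expected a 3D volume (H, W, T), got shape {data.shape}")
    frames = np.moveaxis(data, -1, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    if (frame_interval_ms is None) == (frame_times is None):
        raise InputError("give exactly one of frame_interval_ms / frame_times")
    if frame_times is None:
        frame_times = np.arange(frames.shape[0]) * float(frame_interval_ms)
    return VelocitySeries(frames=frames, pixel_spacing=spacing,
                          frame_times=np.asarray(frame_times, float), venc=venc)


def load_roi_mask(path) -> RoiMask:
    """Read a binary ROI mask from a NIfTI volume (2D, or frames on the
    last axis; nonzero = vessel)."""
    import nibabel as nib

    data = np.squeeze(np.asarray(nib.load(str(path)).get_fdata()))
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    return RoiMask(mask=data != 0)
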