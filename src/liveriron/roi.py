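"""Co-registered circular ROI placement and per-patient R2* summary.

The study design uses three liver ROIs (two right lobe, one left lobe)
with identical geometry applied to every sequence; the per-patient,
per-sequence value is the unweighted mean of the three ROI means.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .synth import LIVER, VESSEL, PhantomSpec

__all__ = [
    "RoiSpec",
    "PatientMeasurement",
    "roi_mask",
    "patient_r2star",
    "default_rois",
    "rois_to_json",
    "rois_from_json",
]

ROI_LABELS = ("right_lobe_1", "right_lobe_2", "left_lobe")

#: acceptable mask area range in cm^2 for the default 10-13 mm diameters
AREA_BOUNDS_CM2 = (0.72, 1.15)


@dataclass(frozen=True)
class RoiSpec:
    """One circular ROI: (row, col) center in pixels, diameter in mm."""

    center: tuple[float, float]
    diameter: float
    label: str

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")


@dataclass(frozen=True)
class PatientMeasurement:
    patient_id: str
    per_sequence_r2star: dict[str, float]
    rois: tuple[RoiSpec, ...]


def roi_mask(spec: RoiSpec, grid_shape: tuple[int, int],
             pixel_spacing: float) -> np.ndarray:
    """Rasterize the ROI circle with the pixel-center inclusion rule.

    A pixel belongs to the mask iff its center lies within ``diameter/2``
    of the ROI center.  If the resulting area falls outside the protocol's
    0.72-1.15 cm^2 window a warning is raised (the mask is still returned);
    a sub-pixel circle degenerates to the single nearest pixel.
    """
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    nr, nc = grid_shape
    r0, c0 = spec.center
    radius_px = 0.5 * spec.diameter / pixel_spacing
    if r0 - radius_px < -0.5 or r0 + radius_px > nr - 0.5 or \
       c0 - radius_px < -0.5 or c0 + radius_px > nc - 0.5:
        raise ValueError("ROI circle does not fit inside the grid")
    rows, cols = np.mgrid[0:nr, 0:nc]
    mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px ** 2
    if not mask.any():
        nearest = (int(round(r0)), int(round(c0)))
        mask[nearest] = True
    area_cm2 = mask.sum() * (pixel_spacing / 10.0) ** 2
    lo, hi = AREA_BOUNDS_CM2
    if not lo <= area_cm2 <= hi:
        warnings.warn(f"ROI {spec.label!r} area {area_cm2:.3f} cm^2 outside "
                      f"[{lo}, {hi}] cm^2", stacklevel=2)
    return mask


def patient_r2star(maps_by_sequence: dict[str, np.ndarray],
                   rois: tuple[RoiSpec, ...] | list[RoiSpec],
                   pixel_spacing: float,
                   patient_id: str = "") -> PatientMeasurement:
    """Mean of the three ROI means, per sequence, with shared ROI geometry.

    The same masks are applied to every sequence's R2* map (co-registration
    by construction); the summary is the unweighted mean of ROI means, not
    the pooled-pixel mean.
    """
    rois = tuple(rois)
    if len(rois) != 3:
        raise ValueError("exactly three ROIs are required")
    shapes = {m.shape for m in maps_by_sequence.values()}
    if len(shapes) != 1:
        raise ValueError("all sequence maps must share one grid")
    grid_shape = shapes.pop()
    masks = [roi_mask(r, grid_shape, pixel_spacing) for r in rois]
    values = {}
    for name, r2map in maps_by_sequence.items():
        roi_means = [float(np.nanmean(r2map[m])) for m in masks]
        values[name] = float(np.mean(roi_means))
    return PatientMeasurement(patient_id=patient_id,
                              per_sequence_r2star=values, rois=rois)


def default_rois(phantom: PhantomSpec,
                 diameter_mm: float = 12.0) -> tuple[RoiSpec, ...]:
    """Place the three standard ROIs inside the phantom liver, off-vessel.

    Two ROIs sit in the vessel-free halves of the "right lobe" (grid left)
    and one in the "left lobe" (grid right); placement is validated against
    the label map so every ROI pixel is liver parenchyma.
    """
    r0, c0 = phantom.liver_center
    ar, ac = phantom.liver_axes
    radius_px = 0.5 * diameter_mm / phantom.pixel_spacing
    labels = phantom.label_map()
    candidates = {
        "right_lobe_1": (r0 - 0.45 * ar, c0 - 0.45 * ac),
        "right_lobe_2": (r0 + 0.45 * ar, c0 - 0.45 * ac),
        "left_lobe": (r0, c0 + 0.55 * ac),
    }
    rois = []
    for label, center in candidates.items():
        spec = RoiSpec(center=center, diameter=diameter_mm, label=label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = roi_mask(spec, phantom.grid_shape, phantom.pixel_spacing)
        if np.any(labels[mask] != LIVER):
            # nudge away from vessels/background toward the liver center
            shifted = _nudge(center, (r0, c0), labels, radius_px, phantom)
            spec = RoiSpec(center=shifted, diameter=diameter_mm, label=label)
        rois.append(spec)
    return tuple(rois)


def _nudge(center, liver_center, labels, radius_px, phantom, steps=12):
    r0, c0 = center
    lr, lc = liver_center
    for k in range(1, steps + 1):
        t = k / steps
        cand = (r0 + t * (lr - r0) * 0.5, c0 + t * (lc - c0) * 0.5)
        rows, cols = np.mgrid[0:phantom.grid_shape[0], 0:phantom.grid_shape[1]]
        mask = (rows - cand[0]) ** 2 + (cols - cand[1]) ** 2 <= radius_px ** 2
        if mask.any() and np.all(labels[mask] == LIVER):
            return cand
    return center


def rois_to_json(rois) -> str:
    return json.dumps([{"center": list(r.center), "diameter": r.diameter,
                        "label": r.label} for r in rois], indent=2)


def rois_from_json(text: str) -> tuple[RoiSpec, ...]:
    return tuple(RoiSpec(center=tuple(d["center"]), diameter=d["diameter"],
                         label=d["label"]) for d in json.loads(text))
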