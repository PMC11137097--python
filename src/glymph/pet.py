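"""Amyloid-PET quantification: SUV, SUVR and the centiloid scale.

SUV normalises a static activity image by injected dose per body weight:

    SUV = activity [kBq/mL] / (ID [MBq] / BW [kg])

SUVR divides the SUV image by the mean SUV of a reference region (the
cerebellum for PiB), and the centiloid scale linearly rescales a global
cortical SUVR so that a young-control anchor maps to 0 and a typical-AD
anchor to 100:

    CL = 100 * (SUVR - SUVR_yc) / (SUVR_ad100 - SUVR_yc)

Values outside [0, 100] are permitted — the scale is open-ended.  Anchor
SUVRs are calibration inputs that depend on tracer and pipeline; the
shipped defaults are conventional whole-cerebellum PiB values and should
be overridden when a site calibration is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RoiMask, Volume

__all__ = [
    "PetMeta",
    "CentiloidAnchors",
    "suv_image",
    "suvr_image",
    "global_cortical_suvr",
    "centiloid",
    "centiloid_to_suvr",
]


@dataclass(frozen=True)
class PetMeta:
    """Injection metadata needed for SUV."""

    injected_dose_mbq: float
    body_weight_kg: float
    frame_window: str = "50-70 min"

    def __post_init__(self):
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")


@dataclass(frozen=True)
class CentiloidAnchors:
    """Level-2 centiloid calibration anchors (global cortical SUVR units)."""

    suvr_yc: float = 1.009
    suvr_ad100: float = 2.076

    def __post_init__(self):
        if not (self.suvr_ad100 > self.suvr_yc > 0):
            raise ValueError(
                f"anchors must satisfy suvr_ad100 > suvr_yc > 0, "
                f"got {self.suvr_ad100}, {self.suvr_yc}"
            )


def suv_image(activity: Volume, meta: PetMeta) -> Volume:
    """Voxelwise SUV from an activity-concentration volume in kBq/mL."""
    if np.any(activity.data < 0):
        raise ValueError("negative activity concentration")
    scale = meta.injected_dose_mbq / meta.body_weight_kg
    return activity.with_data(activity.data / scale, units="unitless")


def suvr_image(suv: Volume, mask: RoiMask, reference: str = "cerebellum") -> Volume:
    """SUV ratio image normalised by the mean SUV of the reference ROI.

    By construction the output's reference-ROI mean is exactly 1.
    """
    sel = mask.boolean(reference)
    if not sel.any():
        raise ValueError(f"reference ROI {reference!r} is empty")
    ref_mean = float(suv.data[sel].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean {ref_mean}")
    return suv.with_data(suv.data / ref_mean, units="unitless")


def global_cortical_suvr(suvr: Volume, mask: RoiMask, cortex: str = "cortex") -> float:
    """Mean SUVR over the designated global cortical ROI."""
    sel = mask.boolean(cortex)
    if not sel.any():
        raise ValueError(f"cortical ROI {cortex!r} is empty")
    return float(suvr.data[sel].mean())


def centiloid(global_suvr: float, anchors: CentiloidAnchors = CentiloidAnchors()) -> float:
    """Linear centiloid transform of a global cortical SUVR."""
    return 100.0 * (global_suvr - anchors.suvr_yc) / (anchors.suvr_ad100 - anchors.suvr_yc)


def centiloid_to_suvr(cl: float, anchors: CentiloidAnchors = CentiloidAnchors()) -> float:
    """Inverse of :func:`centiloid` (used to build synthetic SUVR maps)."""
    return anchors.suvr_yc + cl / 100.0 * (anchors.suvr_ad100 - anchors.suvr_yc)


def quantify(activity: Volume, meta: PetMeta, mask: RoiMask,
             anchors: CentiloidAnchors = CentiloidAnchors()) -> dict[str, float]:
    """SUV/SUVR/centiloid summary row for one subject."""
    suv = suv_image(activity, meta)
    suvr = suvr_image(suv, mask)
    gs = global_cortical_suvr(suvr, mask)
    return {
        "suv_cortex_mean": float(suv.data[mask.boolean("cortex")].mean()),
        "suv_cerebellum_mean": float(suv.data[mask.boolean("cerebellum")].mean()),
        "global_suvr": gs,
        "centiloid": centiloid(gs, anchors),
    }
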