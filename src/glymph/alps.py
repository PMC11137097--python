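"""DTI-ALPS: diffusion-tensor analysis along the perivascular space.

At the level of the lateral-ventricle bodies, projection fibres run mainly
along z, association fibres along y, and the perivascular spaces of the
medullary veins along x.  Water diffusivity measured along x in the
projection and association areas is therefore perpendicular to the local
fibres and is read as perivascular (glymphatic) water movement, while
Dyy in the projection area and Dzz in the association area serve as the
fibre-perpendicular, non-perivascular reference:

    ALPS index = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

An index near 1 means minimal perivascular diffusion; larger values mean
greater perivascular diffusivity.  Subcortical-area diffusivities are
extracted and reported for completeness but never enter the index — there
the fibres run parallel to the perivascular spaces, so Dxx mixes fibre and
perivascular diffusion.

Hemispheric indexes are computed first and then averaged per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .dti import TensorFit
from .io import RoiMask, Volume

__all__ = [
    "AlpsRoiDiffusivities",
    "HemisphereAlps",
    "AlpsResult",
    "roi_mean_diffusivities",
    "alps_index",
    "subject_alps",
    "compute_subject_alps",
]

_ZONES = ("proj", "assoc", "subc")


@dataclass(frozen=True)
class AlpsRoiDiffusivities:
    """The nine ROI-mean diffusivities of one hemisphere (mm^2/s).

    The subcortical triple is carried for reporting only.
    """

    dxx_proj: float
    dyy_proj: float
    dzz_proj: float
    dxx_assoc: float
    dyy_assoc: float
    dzz_assoc: float
    dxx_subc: float = np.nan
    dyy_subc: float = np.nan
    dzz_subc: float = np.nan
    hemisphere: str = "L"
    bvalue: float = np.nan

    def __post_init__(self):
        used = (self.dxx_proj, self.dyy_proj, self.dzz_proj,
                self.dxx_assoc, self.dyy_assoc, self.dzz_assoc)
        if not all(np.isfinite(v) and v >= 0 for v in used):
            raise ValueError(f"non-finite or negative ROI diffusivity: {used}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name not in ("hemisphere", "bvalue")}


@dataclass(frozen=True)
class HemisphereAlps:
    index: float
    hemisphere: str
    bvalue: float


@dataclass(frozen=True)
class AlpsResult:
    """Per-subject ALPS outcome for one shell."""

    left: float
    right: float
    index: float
    bvalue: float


def roi_mean_diffusivities(maps: tuple[Volume, Volume, Volume], mask: RoiMask,
                           hemisphere: str, bvalue: float = np.nan,
                           ) -> AlpsRoiDiffusivities:
    """Arithmetic ROI means of the Dxx/Dyy/Dzz maps for one hemisphere.

    ROI names are ``proj_<H>``, ``assoc_<H>`` and optionally ``subc_<H>``.
    NaN voxels (flagged invalid by the tensor fit) are excluded; an ROI
    that is empty after exclusion is an error.
    """
    dxx, dyy, dzz = maps
    values: dict[str, float] = {}
    for zone in _ZONES:
        name = f"{zone}_{hemisphere}"
        optional = zone == "subc"
        if name not in mask.legend:
            if optional:
                for ax in ("dxx", "dyy", "dzz"):
                    values[f"{ax}_{zone}"] = np.nan
                continue
            raise KeyError(f"required ROI {name!r} missing from mask legend")
        sel = mask.boolean(name)
        for ax, vol in (("dxx", dxx), ("dyy", dyy), ("dzz", dzz)):
            vals = vol.data[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                if optional:
                    values[f"{ax}_{zone}"] = np.nan
                    continue
                raise ValueError(f"ROI {name!r} empty after masking invalid voxels")
            values[f"{ax}_{zone}"] = float(vals.mean())
    return AlpsRoiDiffusivities(hemisphere=hemisphere, bvalue=bvalue, **values)


def alps_index(d: AlpsRoiDiffusivities) -> float:
    """mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

    Invariant under uniform positive scaling of all diffusivities; equals 1
    when the four inputs are equal.  Raises on a non-positive denominator.
    """
    num = 0.5 * (d.dxx_proj + d.dxx_assoc)
    den = 0.5 * (d.dyy_proj + d.dzz_assoc)
    if den <= 0:
        raise ValueError(f"non-positive ALPS denominator {den}")
    return num / den


def hemisphere_alps(d: AlpsRoiDiffusivities) -> HemisphereAlps:
    return HemisphereAlps(alps_index(d), d.hemisphere, d.bvalue)


def subject_alps(left: HemisphereAlps, right: HemisphereAlps) -> AlpsResult:
    """Subject-level index: arithmetic mean of the two hemispheric indexes."""
    lb, rb = left.bvalue, right.bvalue
    same = (lb == rb) or (np.isnan(lb) and np.isnan(rb))
    if not same:
        raise ValueError(f"shell mismatch between hemispheres: {lb} vs {rb}")
    return AlpsResult(left.index, right.index,
                      0.5 * (left.index + right.index), lb)


def compute_subject_alps(fit: TensorFit, mask: RoiMask,
                         ) -> tuple[AlpsResult, dict[str, AlpsRoiDiffusivities]]:
    """Full per-subject ALPS from a fitted tensor shell and an ROI mask.

    Returns the result plus the per-hemisphere ROI diffusivities (for the
    per-subject report row).
    """
    dmaps = fit.axis_diffusivities()
    rois = {h: roi_mean_diffusivities(dmaps, mask, h, bvalue=fit.bvalue)
            for h in ("L", "R")}
    res = subject_alps(hemisphere_alps(rois["L"]), hemisphere_alps(rois["R"]))
    return res, rois


def result_row(subject_id: str, res: AlpsResult,
               rois: dict[str, AlpsRoiDiffusivities]) -> dict[str, float | str]:
    """Flatten one subject's ALPS outcome into a TSV-ready record."""
    row: dict[str, float | str] = {
        "subject_id": subject_id,
        "bvalue": res.bvalue,
        "alps_left": res.left,
        "alps_right": res.right,
        "alps_index": res.index,
    }
    for h, d in rois.items():
        for k, v in d.as_dict().items():
            row[f"{k}_{h}"] = v
    return row
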