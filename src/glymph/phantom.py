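"""Synthetic imaging inputs: tensor phantoms, noisy DWI and PET SUVR maps.

The tensor phantom reproduces the geometry the ALPS method assumes at the
lateral-ventricle-body level: per hemisphere, three white-matter bands —
projection fibres (dominant diffusivity along z), association fibres
(dominant along y) and subcortical fibres (dominant along x) — with the
perivascular spaces running along x through the projection and association
bands.  A single gain parameter ``perivascular_gain`` adds to Dxx in those
two bands and is the phantom's one "disease" knob: reducing it mimics
glymphatic impairment and lowers the ALPS index.

DWI is simulated with the monoexponential tensor forward model and
single-coil Rician noise (magnitude of a complex Gaussian perturbation),
the standard model for magnitude MR images; SNR is defined on the
unweighted (b=0) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dti import TensorFit, TensorModel, design_matrix
from .io import GradientTable, RoiMask, Volume
from .pet import CentiloidAnchors, centiloid_to_suvr

__all__ = [
    "ZoneDiffusivities",
    "PhantomSpec",
    "TensorPhantom",
    "make_tensor_phantom",
    "analytic_alps",
    "simulate_dwi",
    "simulate_pet_suvr",
    "fibonacci_directions",
    "alps_protocol",
]


def fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([
        np.sin(polar) * np.cos(azim),
        np.sin(polar) * np.sin(azim),
        np.cos(polar),
    ])


def alps_protocol(n_dirs: int = 30, shells: tuple[float, ...] = (1000.0, 2000.0),
                  n_b0: int = 1) -> GradientTable:
    """The study's DWI protocol: b=0 frame(s) plus ``n_dirs`` isotropically
    distributed directions repeated on each shell (defaults: 1 + 30 x 2 = 61
    frames at b = 0/1000/2000 s/mm^2)."""
    dirs = fibonacci_directions(n_dirs)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in shells:
        bvals.extend([b] * n_dirs)
        bvecs.extend(dirs)
    return GradientTable(np.asarray(bvals), np.vstack(bvecs))


@dataclass(frozen=True)
class ZoneDiffusivities:
    """Ground-truth diagonal diffusivities (Dxx, Dyy, Dzz) of one zone, mm^2/s."""

    dxx: float
    dyy: float
    dzz: float

    def __post_init__(self):
        if min(self.dxx, self.dyy, self.dzz) < 0:
            raise ValueError("negative diffusivity")

    def as_array(self) -> np.ndarray:
        return np.array([self.dxx, self.dyy, self.dzz])


# Defaults give analytic ALPS = (0.90 + 0.08)/0.70 ~= 1.4, a cognitively
# normal level; lowering perivascular_gain to ~0.01e-3 gives AD-like ~1.3.
_DEFAULT_ZONES = {
    "proj": ZoneDiffusivities(0.90e-3, 0.70e-3, 1.70e-3),   # z-dominant
    "assoc": ZoneDiffusivities(0.90e-3, 1.70e-3, 0.70e-3),  # y-dominant
    "subc": ZoneDiffusivities(1.70e-3, 0.70e-3, 0.70e-3),   # x-dominant
    "background": ZoneDiffusivities(0.80e-3, 0.80e-3, 0.80e-3),
    "cerebellum": ZoneDiffusivities(0.80e-3, 0.80e-3, 0.80e-3),
    "cortex": ZoneDiffusivities(0.80e-3, 0.80e-3, 0.80e-3),
}

DEFAULT_PERIVASCULAR_GAIN = 0.08e-3


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground truth of the three-zone ALPS phantom.

    The grid uses the study's DWI resolution by default (1.9 x 1.9 mm in
    plane, 3.0 mm slices).  ``perivascular_gain`` (mm^2/s) is added to Dxx
    in the projection and association bands only.
    """

    shape: tuple[int, int, int] = (48, 48, 14)
    spacing: tuple[float, float, float] = (1.9, 1.9, 3.0)
    zones: dict = field(default_factory=lambda: dict(_DEFAULT_ZONES))
    perivascular_gain: float = DEFAULT_PERIVASCULAR_GAIN
    s0: float = 1.0
    snr: float | None = 30.0        # None means noiseless

    def __post_init__(self):
        if self.perivascular_gain < 0:
            raise ValueError("perivascular gain must be >= 0")
        if self.s0 <= 0:
            raise ValueError("S0 must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")
        for zone in _DEFAULT_ZONES:
            if zone not in self.zones:
                raise ValueError(f"missing zone {zone!r}")
        # dominance may tie (an isotropic phantom is a valid degenerate case)
        p, a, s = (self.zones[z] for z in ("proj", "assoc", "subc"))
        if p.dzz < max(p.dxx + self.perivascular_gain, p.dyy):
            raise ValueError("projection zone must be z-dominant")
        if a.dyy < max(a.dxx + self.perivascular_gain, a.dzz):
            raise ValueError("association zone must be y-dominant")
        if s.dxx < max(s.dyy, s.dzz):
            raise ValueError("subcortical zone must be x-dominant")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.spacing, 1.0])
        return aff

    def effective_zone(self, name: str) -> ZoneDiffusivities:
        """Zone diffusivities with the perivascular gain applied."""
        z = self.zones[name]
        if name in ("proj", "assoc"):
            return replace(z, dxx=z.dxx + self.perivascular_gain)
        return z

    def with_gain(self, g: float) -> "PhantomSpec":
        return replace(self, perivascular_gain=g)


def analytic_alps(spec: PhantomSpec) -> float:
    """Ground-truth ALPS index implied by the zone tensors."""
    p = spec.effective_zone("proj")
    a = spec.effective_zone("assoc")
    return 0.5 * (p.dxx + a.dxx) / (0.5 * (p.dyy + a.dzz))


@dataclass
class TensorPhantom:
    field: TensorFit            # ground-truth diagonal tensors, exact "fit"
    mask: RoiMask
    analytic_alps: float
    spec: PhantomSpec


def _zone_geometry(shape: tuple[int, int, int]) -> dict[str, tuple]:
    """Voxel-slab extents for each zone, scaled to the grid size."""
    nx, ny, nz = shape
    if nx < 16 or ny < 16 or nz < 6:
        raise ValueError(f"grid {shape} too small for the three-zone geometry")

    def yband(lo_frac, hi_frac):
        lo, hi = int(round(ny * lo_frac)), int(round(ny * hi_frac))
        if hi <= lo:
            raise ValueError("empty band at this grid size")
        return lo, hi

    zlo, zhi = max(1, int(round(nz * 0.55))), nz - 1      # ventricle-body slab
    left = (max(1, int(round(nx * 0.08))), nx // 2 - 1)
    right = (nx // 2 + 1, min(nx - 1, int(round(nx * 0.92))))
    bands = {
        "proj": yband(0.08, 0.22),
        "assoc": yband(0.30, 0.44),
        "subc": yband(0.52, 0.66),
    }
    geo: dict[str, tuple] = {}
    for zone, (ylo, yhi) in bands.items():
        geo[f"{zone}_L"] = (left, (ylo, yhi), (zlo, zhi))
        geo[f"{zone}_R"] = (right, (ylo, yhi), (zlo, zhi))
    # cortex band behind the fibre zones, cerebellum at the inferior slices
    geo["cortex"] = ((left[0], right[1]), yband(0.72, 0.88), (zlo, zhi))
    geo["cerebellum"] = ((nx // 3, 2 * nx // 3), (ny // 3, 2 * ny // 3),
                         (0, max(1, int(round(nz * 0.3)))))
    return geo


def make_tensor_phantom(spec: PhantomSpec = PhantomSpec()) -> TensorPhantom:
    """Build the three-zone tensor field, its ROI mask and the analytic ALPS.

    Zones are axis-aligned slabs (disjoint by construction, validated);
    voxels outside every named zone take the isotropic background tensor.
    """
    geo = _zone_geometry(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.int32)
    legend: dict[str, int] = {}
    comps = np.zeros(spec.shape + (6,), dtype=float)
    bg = spec.zones["background"].as_array()
    comps[..., :3] = bg

    for n, (name, ((x0, x1), (y0, y1), (z0, z1))) in enumerate(geo.items(), start=1):
        zone = name.rsplit("_", 1)[0] if name[-2:] in ("_L", "_R") else name
        block = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
        if labels[block].any():
            raise ValueError(f"zone {name!r} overlaps a previous zone")
        if labels[block].size == 0:
            raise ValueError(f"zone {name!r} is empty at grid {spec.shape}")
        labels[block] = n
        legend[name] = n
        comps[block + (slice(0, 3),)] = spec.effective_zone(zone).as_array()

    mask = RoiMask(labels, legend, spec.affine)
    # represent the ground truth in the same container the fit produces,
    # with a b0-only table standing in for "no fit performed"
    truth = TensorFit(
        model=None,
        components=comps,
        s0=np.full(spec.shape, spec.s0),
        valid=np.ones(spec.shape, dtype=bool),
        clamped=np.zeros(spec.shape, dtype=bool),
        bvalue=np.nan,
        affine=spec.affine,
    )
    return TensorPhantom(truth, mask, analytic_alps(spec), spec)


def simulate_dwi(field: TensorFit, table: GradientTable, s0: float | np.ndarray = 1.0,
                 snr: float | None = None,
                 rng: np.random.Generator | int | None = None) -> Volume:
    """Forward-simulate a 4-D DWI volume from a tensor field.

    Noiseless signal per frame i: ``S_i = S0 * exp(-b_i g_i^T D g_i)``.
    With finite ``snr``, single-coil Rician noise is applied as the
    magnitude of (S + N(0, sigma), N(0, sigma)) with sigma = mean(S0)/snr.
    ``snr=None`` bypasses the noise path exactly.
    """
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), field.components.shape[:-1])
    if np.any(s0 < 0):
        raise ValueError("negative S0")
    X = design_matrix(table)[:, 1:]                      # (n, 6)
    exponent = np.einsum("...c,nc->...n", field.components, X)
    signal = s0[..., None] * np.exp(exponent)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive or None")
        rng = np.random.default_rng(rng)
        sigma = float(np.mean(s0)) / snr
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        signal = np.hypot(re, im)
    return Volume(signal, field.affine.copy(), units="a.u.")


def simulate_pet_suvr(mask: RoiMask, target_centiloid: float,
                      anchors: CentiloidAnchors = CentiloidAnchors(),
                      background: float = 0.25) -> Volume:
    """Synthetic SUVR map whose global cortical value maps to ``target_centiloid``.

    The cerebellum is set to 1 by construction (it is the SUVR reference),
    the cortical ROI to the SUVR the inverse centiloid transform demands,
    and everything else to a low background.
    """
    if "cerebellum" not in mask.legend:
        raise ValueError("mask must define a cerebellum ROI")
    if "cortex" not in mask.legend:
        raise ValueError("mask must define a cortex ROI")
    data = np.full(mask.labels.shape, float(background))
    data[mask.boolean("cerebellum")] = 1.0
    data[mask.boolean("cortex")] = centiloid_to_suvr(target_centiloid, anchors)
    return Volume(data, mask.affine.copy(), units="unitless")


def fit_phantom_alps(spec: PhantomSpec, table: GradientTable | None = None,
                     rng: np.random.Generator | int | None = None,
                     ) -> dict[float, float]:
    """Phantom -> DWI -> per-shell tensor fit -> subject ALPS, in one call.

    Returns ``{shell_b: subject ALPS index}``.  Convenience for tests and
    end-to-end runs.
    """
    from .alps import compute_subject_alps
    from .dti import split_shells

    phantom = make_tensor_phantom(spec)
    if table is None:
        table = alps_protocol()
    dwi = simulate_dwi(phantom.field, table, s0=spec.s0, snr=spec.snr, rng=rng)
    out: dict[float, float] = {}
    for b, (shell_dwi, shell_tab) in split_shells(dwi, table).items():
        fit = TensorModel(shell_tab).fit(shell_dwi)
        res, _ = compute_subject_alps(fit, phantom.mask)
        out[b] = res.index
    return out
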