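"""Per-voxel diffusion-tensor fitting and axis-aligned diffusivity maps.

The ALPS analysis needs the *diagonal* tensor elements Dxx, Dyy, Dzz in the
scanner/image axis frame — diffusivity along fixed anatomical axes — not
eigenvalues.  :meth:`TensorFit.axis_diffusivities` therefore returns the
diagonal of the fitted tensor directly and never eigen-decomposes.

Fitting model: monoexponential tensor signal

    S_i = S0 * exp(-b_i g_i^T D g_i)

estimated per voxel by log-linear least squares with one iteratively
reweighted pass (weights = squared predicted signal), which approximates
the optimal weighting for log-transformed Rician/Gaussian noise.  Shells
are fitted separately (all b=0 frames plus one shell's weighted frames),
mirroring protocols that report one tensor per b-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GradientTable, Volume, SHELL_TOLERANCE

__all__ = [
    "TensorModel",
    "TensorFit",
    "split_shells",
    "fit_tensor",
    "axis_diffusivities",
    "design_matrix",
    "COMPONENT_ORDER",
]

#: order of the six unique tensor components everywhere in this package
COMPONENT_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

#: signals are floored at this fraction of the estimated S0 before the log
SIGNAL_FLOOR_FRACTION = 1e-6

MIN_DIRECTIONS_PER_SHELL = 6


def design_matrix(table: GradientTable) -> np.ndarray:
    """(n_frames, 7) design for the log-linear tensor model.

    Columns: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    acting on the parameter vector [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].
    """
    b = table.bvals
    g = table.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2.0 * b * g[:, 0] * g[:, 1],
        -2.0 * b * g[:, 0] * g[:, 2],
        -2.0 * b * g[:, 1] * g[:, 2],
    ])


def split_shells(dwi: Volume, table: GradientTable,
                 tol: float = SHELL_TOLERANCE) -> dict[float, tuple[Volume, GradientTable]]:
    """Split a multi-shell acquisition into per-shell datasets.

    Each returned dataset holds every b=0 frame plus that shell's weighted
    frames, keyed by the nominal shell b-value.  Raises if there is no b=0
    frame or a shell carries fewer than 6 directions.
    """
    if dwi.n_frames != len(table):
        raise ValueError(
            f"DWI has {dwi.n_frames} frames but gradient table has {len(table)}"
        )
    b0 = table.b0_mask
    if not b0.any():
        raise ValueError("no b=0 frame in acquisition")
    centers = table.shell_centers(tol)
    if not centers:
        raise ValueError("no diffusion-weighted frames (all b=0)")
    data4 = dwi.data if dwi.data.ndim == 4 else dwi.data[..., None]
    out: dict[float, tuple[Volume, GradientTable]] = {}
    for c in centers:
        keep = b0 | table.shell_mask(c, tol)
        n_dirs = int(table.shell_mask(c, tol).sum())
        if n_dirs < MIN_DIRECTIONS_PER_SHELL:
            raise ValueError(f"shell b={c:g} has only {n_dirs} directions (need >= 6)")
        sub = Volume(data4[..., keep], dwi.affine.copy(), dwi.units, dwi.allow_nan)
        subtab = GradientTable(table.bvals[keep], table.bvecs[keep])
        out[c] = (sub, subtab)
    return out


@dataclass
class TensorFit:
    """Result of a per-voxel tensor fit on one shell.

    ``components`` is stacked in :data:`COMPONENT_ORDER` on the last axis;
    diagonal elements are clamped to be non-negative on valid voxels, with
    clamped voxels recorded in ``clamped``.  ``valid`` marks voxels where
    the fit succeeded (finite signals after flooring, full-rank design).
    """

    model: "TensorModel"
    components: np.ndarray           # (..., 6)
    s0: np.ndarray                   # (...)
    valid: np.ndarray                # (...), bool
    clamped: np.ndarray              # (...), bool
    bvalue: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def dxx(self) -> np.ndarray:
        return self.components[..., 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.components[..., 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.components[..., 2]

    @property
    def mean_diffusivity(self) -> np.ndarray:
        # trace/3 convenience; not part of the ALPS analysis proper
        return self.components[..., :3].mean(axis=-1)

    def tensor(self) -> np.ndarray:
        """Full symmetric (..., 3, 3) tensor array."""
        c = self.components
        t = np.empty(c.shape[:-1] + (3, 3), dtype=c.dtype)
        t[..., 0, 0] = c[..., 0]
        t[..., 1, 1] = c[..., 1]
        t[..., 2, 2] = c[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = c[..., 3]
        t[..., 0, 2] = t[..., 2, 0] = c[..., 4]
        t[..., 1, 2] = t[..., 2, 1] = c[..., 5]
        return t

    def axis_diffusivities(self) -> tuple[Volume, Volume, Volume]:
        """Dxx, Dyy, Dzz maps in the image axis frame (NaN on invalid voxels).

        These are the tensor's diagonal entries, deliberately not
        eigenvalues: the perivascular index is defined along fixed axes.
        """
        maps = []
        for k in range(3):
            m = self.components[..., k].astype(float).copy()
            m[~self.valid] = np.nan
            maps.append(Volume(m, self.affine.copy(), units="mm^2/s", allow_nan=True))
        return tuple(maps)


class TensorModel:
    """Log-linear WLS diffusion tensor model for a single-shell dataset.

    Parameters
    ----------
    table : GradientTable
        Must contain at least one b=0 frame and 6 weighted directions, and
        at most one nonzero shell (use :func:`split_shells` first).
    """

    def __init__(self, table: GradientTable):
        centers = table.shell_centers()
        if len(centers) > 1:
            raise ValueError(
                f"multiple shells {centers} in one fit; split_shells() first"
            )
        if not table.b0_mask.any():
            raise ValueError("tensor fit needs at least one b=0 frame")
        self.table = table
        self.bvalue = centers[0] if centers else 0.0
        self.design = design_matrix(table)
        if np.linalg.matrix_rank(self.design) < 7:
            raise ValueError(
                "rank-deficient gradient design: need >= 6 independent "
                "directions plus a b=0 frame"
            )

    def fit(self, data: Volume | np.ndarray,
            mask: np.ndarray | None = None) -> TensorFit:
        """Fit every voxel; returns a :class:`TensorFit`.

        Voxels with non-finite or non-positive b=0 signal are marked invalid
        rather than aborting the fit.
        """
        if isinstance(data, Volume):
            arr = data.data
            affine = data.affine.copy()
        else:
            arr = np.asarray(data, dtype=float)
            affine = np.eye(4)
        if arr.ndim == 3:
            arr = arr[..., None]
        if arr.shape[-1] != len(self.table):
            raise ValueError(
                f"data has {arr.shape[-1]} frames, table has {len(self.table)}"
            )
        spatial = arr.shape[:-1]
        sig = arr.reshape(-1, arr.shape[-1]).astype(float)

        if mask is None:
            mask_flat = np.ones(sig.shape[0], dtype=bool)
        else:
            mask_flat = np.asarray(mask, dtype=bool).reshape(-1)

        s0_est = sig[:, self.table.b0_mask].mean(axis=1)
        usable = mask_flat & np.isfinite(s0_est) & (s0_est > 0)
        usable &= np.all(np.isfinite(sig), axis=1)

        comps = np.full(sig.shape[0] * 6, np.nan).reshape(sig.shape[0], 6)
        s0_out = np.full(sig.shape[0], np.nan)
        clamped = np.zeros(sig.shape[0], dtype=bool)

        if usable.any():
            s = sig[usable]
            floor = SIGNAL_FLOOR_FRACTION * s0_est[usable, None]
            y = np.log(np.maximum(s, floor))
            X = self.design
            # OLS start
            beta = np.linalg.lstsq(X, y.T, rcond=None)[0].T  # (v, 7)
            # one IRLS pass: weights = squared predicted signal
            w = np.exp(2.0 * (beta @ X.T))  # (v, n)
            A = np.einsum("vn,ni,nj->vij", w, X, X)
            rhs = np.einsum("vn,ni,vn->vi", w, X, y)
            beta = np.linalg.solve(A, rhs[..., None])[..., 0]
            comps[usable] = beta[:, 1:]
            s0_out[usable] = np.exp(beta[:, 0])
            # physical constraint: diagonal diffusivities are non-negative
            diag = comps[usable][:, :3]
            neg = diag < 0
            if neg.any():
                flags = clamped[usable]
                flags[neg.any(axis=1)] = True
                clamped[usable] = flags
                diag[neg] = 0.0
                comps[usable, :3] = diag

        return TensorFit(
            model=self,
            components=comps.reshape(spatial + (6,)),
            s0=s0_out.reshape(spatial),
            valid=usable.reshape(spatial),
            clamped=clamped.reshape(spatial),
            bvalue=self.bvalue,
            affine=affine,
        )


def fit_tensor(shell_dwi: Volume, shell_table: GradientTable,
               mask: np.ndarray | None = None) -> TensorFit:
    """Functional wrapper: ``TensorModel(table).fit(dwi)``."""
    return TensorModel(shell_table).fit(shell_dwi, mask=mask)


def axis_diffusivities(fit: TensorFit) -> tuple[Volume, Volume, Volume]:
    """Functional wrapper for :meth:`TensorFit.axis_diffusivities`."""
    return fit.axis_diffusivities()
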