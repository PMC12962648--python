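"""Single-tensor fitting and scalar diffusion maps.

Per voxel, the diffusion signal is modeled as

    S(b, g) = S0 * exp(-b * g' D g)

with D a symmetric 3x3 tensor in mm2/s.  Fitting is log-linear weighted
least squares in two passes: an ordinary least-squares pass initializes
the tensor, then a second pass re-weights by the squared predicted
signal (the standard variance model for log-transformed Rician data).
Scalar maps (FA, MD, eigenvalues) use eigenvalues clamped at zero; the
axis diffusivities Dxx/Dyy/Dzz are read from the raw tensor diagonal,
because the ALPS index is defined on image-axis diffusivities, not
eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glymph.scheme import AcquisitionScheme

__all__ = [
    "DiffusionVolume",
    "TensorField",
    "ScalarMaps",
    "design_matrix",
    "fit_tensor",
    "tensor_metrics",
    "fa_from_eigenvalues",
]

# order of the 6 unique tensor components everywhere in this module
TENSOR_COMPONENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class DiffusionVolume:
    """A 4D diffusion-weighted series with its gradient table."""

    signal: np.ndarray  # (x, y, z, n) nonnegative
    scheme: AcquisitionScheme
    voxel_size: float | tuple[float, float, float] = 1.0
    brain_mask: np.ndarray | None = None  # (x, y, z) bool

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"{self.signal.shape[3]} volumes but scheme has {len(self.scheme)}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be nonnegative")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.signal.shape[:3]:
                raise ValueError("brain_mask grid does not match signal grid")
            if not self.brain_mask.any():
                raise ValueError("brain_mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class TensorField:
    """Per-voxel symmetric tensor (mm2/s) + baseline signal."""

    d: np.ndarray  # (x, y, z, 6) in TENSOR_COMPONENTS order
    s0: np.ndarray  # (x, y, z)
    fit_ok: np.ndarray  # (x, y, z) bool

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s0.shape

    def as_matrix(self) -> np.ndarray:
        """Full (x, y, z, 3, 3) symmetric tensor array."""
        dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(self.d, -1, 0)
        m = np.empty(self.shape + (3, 3), dtype=float)
        m[..., 0, 0] = dxx
        m[..., 1, 1] = dyy
        m[..., 2, 2] = dzz
        m[..., 0, 1] = m[..., 1, 0] = dxy
        m[..., 0, 2] = m[..., 2, 0] = dxz
        m[..., 1, 2] = m[..., 2, 1] = dyz
        return m


@dataclass
class ScalarMaps:
    """Voxelwise scalar maps derived from a tensor field."""

    fa: np.ndarray
    md: np.ndarray
    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    eigenvalues: np.ndarray  # (x, y, z, 3) ascending
    fit_ok: np.ndarray


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n, 7) log-signal design: columns [1, -b gx2, -b gy2, -b gz2,
    -2b gx gy, -2b gx gz, -2b gy gz] so that B @ [ln S0, D6] = ln S."""
    b = scheme.bvals
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def _batched_wls(B: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Solve per-row weighted LS: argmin_th ||sqrt(w_v) (B th - y_v)||.

    B (n, p); y, w (v, n).  Returns (v, p).  Chunked to bound memory.
    """
    v, n = y.shape
    p = B.shape[1]
    out = np.empty((v, p))
    chunk = max(1, int(4e6 // (n * p)))
    for lo in range(0, v, chunk):
        hi = min(v, lo + chunk)
        Bw = B[None, :, :] * w[lo:hi, :, None]  # (c, n, p)
        M = np.einsum("cnp,nq->cpq", Bw, B)
        r = np.einsum("cnp,cn->cp", Bw, y[lo:hi])
        try:
            out[lo:hi] = np.linalg.solve(M, r[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # singular voxels: fall back one by one
            for i in range(lo, hi):
                try:
                    out[i] = np.linalg.solve(M[i - lo], r[i - lo])
                except np.linalg.LinAlgError:
                    out[i] = np.nan
    return out


def fit_tensor(dwi: DiffusionVolume) -> TensorField:
    """Two-pass WLS single-tensor fit on the log signal.

    Pass 1 is OLS on ln S; pass 2 re-weights with the squared predicted
    signal from pass 1.  Voxels with nonpositive b0 signal (or outside
    the brain mask) are flagged ``fit_ok=False`` rather than raising.
    """
    scheme = dwi.scheme
    if len(scheme) < 7:
        raise ValueError("need at least 7 volumes (1 b0 + 6 directions)")
    B = design_matrix(scheme)

    shape = dwi.shape
    mask = dwi.brain_mask if dwi.brain_mask is not None else np.ones(shape, bool)
    sig = dwi.signal[mask]  # (v, n)

    b0_mean = sig[:, scheme.b0_mask].mean(axis=1)
    usable = b0_mean > 0

    d = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    fit_ok = np.zeros(shape, dtype=bool)
    if usable.any():
        s_use = sig[usable]
        floor = 1e-6 * b0_mean[usable][:, None]
        y = np.log(np.maximum(s_use, floor))

        # pass 1: OLS (shared pseudoinverse)
        theta = y @ np.linalg.pinv(B).T  # (v, 7)
        # pass 2: WLS, weights = predicted signal squared
        pred = np.exp(np.clip(theta @ B.T, -50.0, 50.0))
        theta = _batched_wls(B, y, pred**2)

        ok = np.all(np.isfinite(theta), axis=1)
        theta[~ok] = 0.0

        vox_idx = np.flatnonzero(mask.ravel())[usable]
        flat_d = d.reshape(-1, 6)
        flat_d[vox_idx] = theta[:, 1:]
        s0.ravel()[vox_idx] = np.exp(np.clip(theta[:, 0], -50.0, 50.0))
        fit_ok.ravel()[vox_idx] = ok
    return TensorField(d=d, s0=s0, fit_ok=fit_ok)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam|| (0 where ||lam|| = 0)."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(evals - mean, axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def tensor_metrics(tf: TensorField) -> ScalarMaps:
    """FA/MD/eigenvalues (clamped >= 0) and raw-diagonal axis diffusivities."""
    mats = tf.as_matrix()
    evals = np.linalg.eigvalsh(mats)  # ascending
    evals_c = np.clip(evals, 0.0, None)
    fa = fa_from_eigenvalues(evals_c)
    md = evals_c.mean(axis=-1)
    fa = np.where(tf.fit_ok, fa, 0.0)
    md = np.where(tf.fit_ok, md, 0.0)
    return ScalarMaps(
        fa=fa,
        md=md,
        dxx=tf.d[..., 0].copy(),
        dyy=tf.d[..., 1].copy(),
        dzz=tf.d[..., 2].copy(),
        eigenvalues=evals_c,
        fit_ok=tf.fit_ok.copy(),
    )
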