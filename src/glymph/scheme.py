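"""Diffusion acquisition schemes (b-values + gradient directions).

A scheme pairs one b-value and one unit gradient direction with every
volume of a 4D diffusion series, FSL bval/bvec style.  Factories provide
the two single-shell protocols this package targets: a b = 1000 s/mm2
acquisition with a configurable number of directions (31-124) and a
b = 2000 s/mm2 / 56-direction acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "fibonacci_directions",
    "b1000_scheme",
    "b2000_scheme",
]

#: b-values at or below this (s/mm2) count as b0 volumes.
B0_THRESHOLD = 50.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Gradient table: per-volume b-values (s/mm2) and unit directions.

    Invariants (checked on construction): every non-b0 direction has unit
    Euclidean norm to 1e-6, there is at least one b0 volume and at least
    6 unique non-b0 directions so a single tensor is identifiable.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3), rows are unit vectors for b > 0
    name: str = ""

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3); got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

        dwi = ~self.b0_mask
        if not np.any(~dwi):
            raise ValueError("scheme has no b0 volume")
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 directions must be unit vectors (tol 1e-6)")
        uniq = np.unique(np.round(bvecs[dwi], 6), axis=0)
        if uniq.shape[0] < 6:
            raise ValueError(
                f"need >= 6 unique non-b0 directions, got {uniq.shape[0]}"
            )

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def shell_bvalue(self) -> float:
        """The single non-zero shell b-value; error if multi-shell."""
        shells = np.unique(self.bvals[~self.b0_mask])
        if shells.size == 0:
            raise ValueError("scheme has no diffusion-weighted shell")
        if shells.size > 1:
            raise ValueError(f"multi-shell scheme (b = {shells}); expected one shell")
        return float(shells[0])


def fibonacci_directions(n: int) -> np.ndarray:
    """`n` roughly uniform unit vectors on the sphere (golden-spiral lattice).

    Deterministic; adequate angular coverage for tensor fitting without
    needing an electrostatic-repulsion table.
    """
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    vecs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def _single_shell(b: float, n_dirs: int, n_b0: int, name: str) -> AcquisitionScheme:
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_dirs)])
    return AcquisitionScheme(bvals, bvecs, name=name)


def b1000_scheme(n_dirs: int = 64, n_b0: int = 1) -> AcquisitionScheme:
    """b = 0 + 1000 s/mm2 single-shell scheme, 31-124 directions."""
    if not 31 <= n_dirs <= 124:
        raise ValueError("the b1000 protocol family uses 31-124 directions")
    return _single_shell(1000.0, n_dirs, n_b0, f"b1000x{n_dirs}")


def b2000_scheme(n_dirs: int = 56, n_b0: int = 1) -> AcquisitionScheme:
    """b = 0 + 2000 s/mm2 single-shell scheme, 56 directions."""
    return _single_shell(2000.0, n_dirs, n_b0, f"b2000x{n_dirs}")
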