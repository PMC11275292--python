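"""Angiography extraction on 2D projection stacks.

Repeated projections of the same location decompose into a dominant
static clutter component, a temporally varying angiography component,
and noise.  Two extractors separate the flow signal:

* eigen-decomposition clutter filtering (ED): project the frames off the
  dominant eigenvectors of their small N x N correlation matrix;
* speckle variance (SV): the per-pixel population variance across the N
  repeats.

On the FT-free path the frames are real-valued (no phase survives the
spectral summation), so the Hermitian transpose degrades to a plain
transpose; the code still conjugates so the same routines serve complex
frame-wise baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .projection import ProjectionStack

__all__ = [
    "AngioProjection",
    "EigenFilterResult",
    "projection_correlation_matrix",
    "select_r_auto",
    "eigen_clutter_filter",
    "rupp_ed",
    "rupp_sv",
]

logger = logging.getLogger(__name__)


@dataclass
class AngioProjection:
    """X x Y nonnegative angiography map Proj_a."""

    values: np.ndarray
    method: str = ""  # rupp_sv | rupp_ed | sv3d | frame_ed | ground_truth_ed

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"angio map must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angio map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("angio map must be nonnegative")


@dataclass
class EigenFilterResult:
    """Diagnostics of one eigen-decomposition clutter filtering run.

    ``correlation`` is the N x N Gram matrix of the frame Casorati rows,
    ``eigenvalues`` are sorted decreasingly with matching ``eigenvectors``
    columns, ``r`` is the number of removed (clutter) eigenvectors and
    ``residual_stack`` the filtered frames.
    """

    correlation: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    r: int
    residual_stack: np.ndarray


def _casorati(frames: np.ndarray) -> np.ndarray:
    """Flatten an (N, X, Y) stack to an N x (X*Y) Casorati matrix
    (frames as rows)."""
    n = frames.shape[0]
    return frames.reshape(n, -1)


def projection_correlation_matrix(stack: ProjectionStack) -> np.ndarray:
    """Signal correlation matrix C = (1/N) * Proj * Proj^H.

    With frames as Casorati rows this is the N x N Gram matrix of the
    repeated projections, Hermitian and positive semidefinite; its
    dominant eigenvectors span the static clutter.
    """
    cas = _casorati(stack.frames)
    # einsum keeps the accumulation order simple and BLAS-free, so the
    # result is reproducible against an explicit loop
    corr = np.einsum("ip,jp->ij", cas, cas.conj()) / stack.N
    return corr


def select_r_auto(eigenvalues: np.ndarray) -> int:
    """Automatic clutter rank: eigenvalues strictly above their mean.

    The clutter component dominates the repeated projections, so the
    eigenvalues that exceed the average of all eigenvalues are attributed
    to static tissue.  May return 0 when all eigenvalues are equal (no
    dominant component, e.g. pure noise).
    """
    ev = np.asarray(eigenvalues, dtype=np.float64)
    if ev.ndim != 1 or ev.size == 0:
        raise ValueError("eigenvalues must be a nonempty 1D array")
    if np.any(np.diff(ev) > 1e-9 * max(abs(ev[0]), 1.0)):
        raise ValueError("eigenvalues must be sorted decreasingly")
    return int(np.sum(ev > ev.mean()))


def eigen_clutter_filter(
    casorati: np.ndarray, r: int | str = "auto"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Core eigen-decomposition clutter rejection on a Casorati matrix.

    Computes C = (1/N) A A^H, its eigen-decomposition with eigenvalues
    sorted decreasingly, removes the top-``r`` eigenvector subspace:

        residual = (Id - sum_{i<=r} e_i e_i^H) A

    Returns (residual, correlation, eigenvalues, eigenvectors, r).
    With ``r=0`` the filter is the identity.
    """
    A = np.asarray(casorati)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("Casorati matrix must be 2D with at least 2 rows")
    n = A.shape[0]
    corr = np.einsum("ip,jp->ij", A, A.conj()) / n
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if r == "auto":
        r_int = select_r_auto(evals)
        if r_int == 0:
            logger.warning(
                "automatic rank selection found no dominant eigenvalue "
                "(all equal); no clutter removed"
            )
    else:
        r_int = int(r)
    if not 0 <= r_int < n:
        raise ValueError(f"removed-eigenvector count r={r_int} must satisfy 0 <= r < N={n}")
    if r_int == 0:
        residual = A.copy()
    else:
        V = evecs[:, :r_int]  # (N, r)
        residual = A - V @ (V.conj().T @ A)
    return residual, corr, evals, evecs, r_int


def rupp_ed(
    stack: ProjectionStack, r: int | str = "auto"
) -> tuple[AngioProjection, EigenFilterResult]:
    """Eigen-decomposition angiography on a 2D projection stack.

    The residual stack after clutter-subspace removal is collapsed to a
    single en-face map as the mean of absolute values over the N repeats.
    """
    frames = stack.frames
    residual, corr, evals, evecs, r_int = eigen_clutter_filter(_casorati(frames), r)
    residual_stack = residual.reshape(frames.shape)
    angio = np.abs(residual_stack).mean(axis=0)
    result = EigenFilterResult(
        correlation=corr,
        eigenvalues=evals,
        eigenvectors=evecs,
        r=r_int,
        residual_stack=residual_stack,
    )
    return AngioProjection(angio, method="rupp_ed"), result


def rupp_sv(stack: ProjectionStack) -> AngioProjection:
    """Speckle-variance angiography on a 2D projection stack.

    Per-pixel population variance across the repeats:
    Proj_a = (1/N) * sum_n (Proj_n - Proj_mean)^2.  Insensitive to any
    static offset common to all frames; scales quadratically with the
    signal.
    """
    frames = stack.frames
    mean = frames.mean(axis=0)
    var = ((frames - mean) ** 2).mean(axis=0)
    return AngioProjection(var, method="rupp_sv")
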