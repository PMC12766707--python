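"""Residue cross-correlation matrices: NDCC and NLMI.

Two complementary measures of correlated residue motion, both computed from
CA fluctuation vectors Delta-r_i(t) = r_i(t) - <r_i> after superposing the
selected frames onto their window mean:

* NDCC (normalized dynamic cross-correlation), range [-1, 1]:

      C_ij = <Delta r_i . Delta r_j> / sqrt(<|Delta r_i|^2> <|Delta r_j|^2>)

  The cosine-like projection loses correlation between perpendicular motions
  and keeps sign.

* NLMI (normalized linear mutual information), range [0, 1]: the Gaussian
  mutual information of the two 3-D fluctuation vectors,

      I_ij = 1/2 [ ln det C_i + ln det C_j - ln det C_ij ]

  with 3x3 marginal and 6x6 joint covariances, mapped onto a correlation
  scale via NLMI_ij = sqrt(1 - exp(-2 I_ij / 3)). NLMI is direction-blind:
  for isotropic Gaussian fluctuations with per-axis correlation r it equals
  |r| exactly, which the synthetic generator exploits for calibration tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_io import Ensemble, EnsembleError
from .trajectory import iterative_mean_structure

__all__ = ["CorrelationMatrix", "ndcc_matrix", "nlmi_matrix"]

# relative ridge added to a singular joint covariance diagonal
_JOINT_RIDGE = 1e-9


class ZeroVarianceError(EnsembleError):
    """A residue shows no motion in the window; its correlation is undefined."""


@dataclass(frozen=True)
class CorrelationMatrix:
    kind: str  # "NDCC" | "NLMI"
    values: np.ndarray  # (R, R), symmetric, unit diagonal
    frame_window: tuple[int, int]
    n_frames_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


def _window_displacements(
    ensemble: Ensemble,
    window: tuple[int, int] | np.ndarray | None,
    superpose: bool = True,
) -> tuple[np.ndarray, tuple[int, int], int]:
    """Superpose window frames onto their mean; return centered (F, R, 3).

    ``superpose=False`` only subtracts the temporal mean per residue. Use it
    for ensembles already expressed in a common laboratory frame (the
    synthetic generators): rigid-body fitting is a no-op there only in
    expectation, and at finite size it actively removes coherent collective
    motion, which is indistinguishable from rigid drift.
    """
    if not ensemble.is_calpha_only():
        raise EnsembleError("correlation matrices are computed on CA-only ensembles")
    if window is None:
        frames = np.arange(ensemble.n_frames)
        span = (0, ensemble.n_frames)
    elif isinstance(window, tuple):
        start, end = window
        if not 0 <= start < end <= ensemble.n_frames:
            raise EnsembleError(f"invalid frame window {window}")
        frames = np.arange(start, end)
        span = (int(start), int(end))
    else:
        frames = np.asarray(window, dtype=int)
        if frames.size == 0:
            raise EnsembleError("empty frame selection")
        span = (int(frames.min()), int(frames.max()) + 1)
    if frames.size < 2:
        raise EnsembleError("correlation needs at least 2 frames in the window")
    coords = ensemble.coordinates[frames]
    if superpose:
        sup, mean = iterative_mean_structure(coords)
    else:
        sup, mean = coords, coords.mean(axis=0)
    disp = sup - mean  # (F, R, 3)
    return disp, span, frames.size


def ndcc_matrix(
    ensemble: Ensemble,
    window: tuple[int, int] | np.ndarray | None = None,
    superpose: bool = True,
) -> CorrelationMatrix:
    """Normalized dynamic cross-correlation over a frame window.

    ``window`` is a half-open (start, end) range, an explicit frame-index
    array (e.g. the union of stable windows), or None for all frames.
    Set ``superpose=False`` for pre-aligned (synthetic) ensembles.
    """
    disp, span, n_used = _window_displacements(ensemble, window, superpose)
    inner = np.einsum("fid,fjd->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner)
    zero = np.where(var <= 1e-300)[0]
    if zero.size:
        raise ZeroVarianceError(
            f"residue {int(zero[0])} has zero positional variance in the window"
        )
    C = inner / np.sqrt(np.outer(var, var))
    C = np.clip((C + C.T) / 2, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(kind="NDCC", values=C, frame_window=span, n_frames_used=n_used)


def nlmi_matrix(
    ensemble: Ensemble,
    window: tuple[int, int] | np.ndarray | None = None,
    superpose: bool = True,
) -> CorrelationMatrix:
    """Normalized linear mutual information over a frame window.

    Gaussian estimate from 3x3 marginal and 6x6 joint fluctuation
    covariances; the diagonal is 1 by convention. A singular joint
    covariance is regularized with a trace-scaled ridge and warned about.
    Set ``superpose=False`` for pre-aligned (synthetic) ensembles.
    """
    disp, span, n_used = _window_displacements(ensemble, window, superpose)
    F, R, _ = disp.shape
    flat = disp.reshape(F, 3 * R)
    # full covariance once, 3x3 / 6x6 blocks sliced per pair
    cov = flat.T @ flat / F
    var = np.einsum("ii->i", cov.reshape(3 * R, 3 * R))
    res_var = var.reshape(R, 3).sum(axis=1)
    zero = np.where(res_var <= 1e-300)[0]
    if zero.size:
        raise ZeroVarianceError(
            f"residue {int(zero[0])} has zero positional variance in the window"
        )
    logdet3 = np.empty(R)
    for i in range(R):
        Ci = cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
        sign, ld = np.linalg.slogdet(Ci)
        if sign <= 0:
            Ci = Ci + _JOINT_RIDGE * (np.trace(Ci) / 3) * np.eye(3)
            sign, ld = np.linalg.slogdet(Ci)
        logdet3[i] = ld
    M = np.eye(R)
    warned = False
    idx = np.arange(3)
    for i in range(R):
        bi = 3 * i + idx
        for j in range(i + 1, R):
            bj = 3 * j + idx
            sel = np.concatenate([bi, bj])
            Cij = cov[np.ix_(sel, sel)]
            sign, ld = np.linalg.slogdet(Cij)
            if sign <= 0 or not np.isfinite(ld):
                Cij = Cij + _JOINT_RIDGE * (np.trace(Cij) / 6) * np.eye(6)
                sign, ld = np.linalg.slogdet(Cij)
                if not warned:
                    warnings.warn(
                        "singular joint covariance regularized with a trace ridge",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    warned = True
            mi = 0.5 * (logdet3[i] + logdet3[j] - ld)
            mi = max(mi, 0.0)  # numerical floor; MI is non-negative
            M[i, j] = M[j, i] = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
    return CorrelationMatrix(kind="NLMI", values=M, frame_window=span, n_frames_used=n_used)
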