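"""Superposition and per-frame / per-residue trajectory metrics.

RMSD plateaus ("stable windows") select the frames that feed correlation
network analysis: correlations estimated across a conformational transition
mix distinct basins and inflate apparent coupling, so only frames from flat
stretches of the RMSD series are used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import Conformation, Ensemble, EnsembleError

__all__ = [
    "SeriesResult",
    "StableWindow",
    "kabsch_superpose",
    "superpose_ensemble",
    "iterative_mean_structure",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "detect_stable_windows",
    "stable_frame_indices",
]


@dataclass(frozen=True)
class SeriesResult:
    """A per-frame (rmsd, rgyr) or per-residue (rmsf) series in Angstrom."""

    values: np.ndarray
    kind: str  # "rmsd" | "rmsf" | "rgyr"
    reference_frame: int | str = 0  # frame index or "mean"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in {"rmsd", "rmsf", "rgyr"}:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if np.any(self.values < -1e-12):
            raise ValueError(f"{self.kind} values must be non-negative")


@dataclass(frozen=True)
class StableWindow:
    """Half-open frame range [start_frame, end_frame) of flat RMSD.

    ``rmsd_std`` is the worst (largest) sliding-window standard deviation
    inside the merged range, so it is guaranteed <= the detection threshold.
    """

    start_frame: int
    end_frame: int
    mean_rmsd: float
    rmsd_std: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def _kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation (det=+1) and the two centroids."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    rot = (U @ D @ Vt).T  # maps mobile-centered coords onto reference frame
    return rot, cm, cr


def kabsch_superpose(mobile: Conformation, reference: Conformation) -> tuple[Conformation, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed conformation and the minimized RMSD. Only proper
    rotations are allowed (det = +1), so a mirror image keeps a nonzero
    residual rather than being reflected away.
    """
    if mobile.n_atoms != reference.n_atoms:
        raise EnsembleError(
            f"atom-count mismatch: {mobile.n_atoms} vs {reference.n_atoms}"
        )
    if mobile.n_atoms < 3:
        raise EnsembleError("superposition needs at least 3 atoms")
    rot, cm, cr = _kabsch_rotation(mobile.coords, reference.coords)
    moved = (mobile.coords - cm) @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference.coords) ** 2, axis=1))))
    out = Conformation(
        coords=moved,
        atom_names=mobile.atom_names,
        elements=mobile.elements,
        residue_indices=mobile.residue_indices,
        residue_names=mobile.residue_names,
        chain_ids=mobile.chain_ids,
        author_residue_numbers=mobile.author_residue_numbers,
        frame_index=mobile.frame_index,
        time_label=mobile.time_label,
    )
    return out, rmsd


def _superpose_coords(coords: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame of (F,A,3) onto ref (A,3); returns coords and rmsds."""
    out = np.empty_like(coords)
    rmsds = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        rot, cm, cr = _kabsch_rotation(coords[f], ref)
        moved = (coords[f] - cm) @ rot.T + cr
        out[f] = moved
        rmsds[f] = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    return out, rmsds


def iterative_mean_structure(coords: np.ndarray, n_iter: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto an iteratively refined mean structure.

    Standard two-pass scheme: superpose onto frame 0, take the mean, then
    superpose onto that mean (repeated ``n_iter`` times). Returns the
    superposed coordinates and the final mean.
    """
    ref = coords[0]
    sup = coords
    for _ in range(n_iter):
        sup, _ = _superpose_coords(coords, ref)
        ref = sup.mean(axis=0)
    sup, _ = _superpose_coords(coords, ref)
    return sup, ref


def superpose_ensemble(ensemble: Ensemble, reference: str = "mean") -> Ensemble:
    """Return an ensemble with every frame rigidly superposed.

    ``reference="first"`` superposes onto frame 0; ``"mean"`` onto the
    two-pass iterative mean structure.
    """
    if reference == "first":
        sup, _ = _superpose_coords(ensemble.coordinates, ensemble.coordinates[0])
    elif reference == "mean":
        sup, _ = iterative_mean_structure(ensemble.coordinates)
    else:
        raise ValueError("reference must be 'first' or 'mean'")
    return ensemble.with_coordinates(sup)


def rmsd_series(ensemble: Ensemble, reference: str = "first") -> SeriesResult:
    """Per-frame RMSD after optimal superposition onto the reference."""
    if ensemble.n_frames < 1:
        raise EnsembleError("empty ensemble")
    if reference == "first":
        _, rmsds = _superpose_coords(ensemble.coordinates, ensemble.coordinates[0])
        ref_label: int | str = 0
    elif reference == "mean":
        sup, mean = iterative_mean_structure(ensemble.coordinates)
        rmsds = np.sqrt(np.mean(np.sum((sup - mean) ** 2, axis=2), axis=1))
        ref_label = "mean"
    else:
        raise ValueError("reference must be 'first' or 'mean'")
    return SeriesResult(values=rmsds, kind="rmsd", reference_frame=ref_label)


def rmsf_per_residue(ensemble: Ensemble, superpose: bool = True) -> SeriesResult:
    """Root-mean-square fluctuation of each atom about its ensemble mean.

    Frames are first superposed onto the iterative mean structure so rigid
    drift does not register as fluctuation. ``superpose=False`` skips the
    fit for ensembles already in a common frame (synthetic generators),
    where fitting would instead absorb genuine collective fluctuation.
    """
    if ensemble.n_frames < 2:
        raise EnsembleError("RMSF needs at least 2 frames")
    if superpose:
        sup, mean = iterative_mean_structure(ensemble.coordinates)
    else:
        sup = ensemble.coordinates
        mean = sup.mean(axis=0)
    dev2 = np.sum((sup - mean) ** 2, axis=2)  # (F, A)
    rmsf = np.sqrt(dev2.mean(axis=0))
    return SeriesResult(values=rmsf, kind="rmsf", reference_frame="mean")


def radius_of_gyration(ensemble: Ensemble, masses: np.ndarray | None = None) -> SeriesResult:
    """Mass-weighted radius of gyration per frame (unit masses in CA mode)."""
    if masses is None:
        masses = np.ones(ensemble.n_atoms)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    com = np.einsum("fad,a->fd", ensemble.coordinates, masses) / total
    dev2 = np.sum((ensemble.coordinates - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("fa,a->f", dev2, masses) / total)
    return SeriesResult(values=rg, kind="rgyr", reference_frame="mean")


def detect_stable_windows(
    rmsd: SeriesResult, window: int, std_max: float
) -> list[StableWindow]:
    """Find maximal flat stretches of an RMSD series.

    A sliding window of ``window`` frames passes when its standard deviation
    is <= ``std_max``; overlapping passing windows are merged into maximal
    runs. Every ``window``-frame sub-window of a reported range satisfies the
    criterion by construction; ``rmsd_std`` records the worst one.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    values = rmsd.values
    n = len(values)
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    # rolling std over each start position (population std, ddof=0)
    stds = np.array([values[s : s + window].std() for s in range(n - window + 1)])
    ok = stds <= std_max
    covered = np.zeros(n, dtype=bool)
    for s in np.where(ok)[0]:
        covered[s : s + window] = True
    windows: list[StableWindow] = []
    f = 0
    while f < n:
        if not covered[f]:
            f += 1
            continue
        start = f
        while f < n and covered[f]:
            f += 1
        end = f
        # every passing window is fully inside exactly one maximal run
        inside = [s for s in np.where(ok)[0] if start <= s and s + window <= end]
        seg = values[start:end]
        windows.append(
            StableWindow(
                start_frame=start,
                end_frame=end,
                mean_rmsd=float(seg.mean()),
                rmsd_std=float(stds[inside].max()),
            )
        )
    return windows


def stable_frame_indices(
    windows: list[StableWindow], n_frames: int
) -> tuple[np.ndarray, bool]:
    """Union of stable-window frames, falling back to the final half.

    Returns (frame indices, used_fallback). The fallback — the last 50% of
    frames — keeps the pipeline alive when no window passes the threshold.
    """
    if windows:
        idx = np.unique(
            np.concatenate([np.arange(w.start_frame, w.end_frame) for w in windows])
        )
        return idx, False
    return np.arange(n_frames // 2, n_frames), True
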