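"""Geometric detection of noncovalent contacts and composition profiling.

Per-conformation detectors for four contact classes, with widely used
geometric cutoffs (all configurable at call time):

* hydrogen bond — donor/acceptor heavy atoms (N/O/S donating to N/O) within
  3.5 A; when explicit hydrogens are present the D-H...A angle must also be
  >= 120 deg;
* hydrophobic — side-chain carbon pair of two apolar residues within 5.0 A;
* salt bridge — basic side-chain nitrogen (Arg NH1/NH2/NE, Lys NZ,
  His ND1/NE2) to acidic carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2)
  within 4.0 A;
* aromatic (pi-pi) — ring centroids of F/Y/W/H within 7.0 A.

One contact is reported per residue pair per frame (the closest qualifying
atom pair), and pairs closer than two positions in sequence are suppressed —
backbone neighbors are trivially in contact. The per-frame counts of a
contact class form an interaction time series whose drift tracks structural
(de)stabilization along a trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_io import Conformation, Ensemble, EnsembleError

__all__ = [
    "NoncovalentContact",
    "InteractionSeries",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_salt_bridges",
    "detect_aromatic",
    "detect_contacts",
    "interaction_time_series",
    "aa_composition",
]

HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR", "CYS"}
)
BASIC_ATOMS = {"ARG": {"NH1", "NH2", "NE"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
MIN_SEQ_SEPARATION = 2  # suppress |i-j| < 2 contacts for all kinds


class UnsupportedTopologyError(EnsembleError):
    """Contact detection needs an all-atom conformation, not CA-only."""


@dataclass(frozen=True)
class NoncovalentContact:
    kind: str  # "hbond" | "hydrophobic" | "salt_bridge" | "aromatic"
    residue_i: int
    residue_j: int  # i < j
    atoms: tuple[str, str]
    distance: float  # A
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.residue_i >= self.residue_j:
            raise ValueError("contacts are stored with residue_i < residue_j")


@dataclass(frozen=True)
class InteractionSeries:
    kind: str
    counts: np.ndarray  # per-frame residue-pair contact counts

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


def _require_all_atom(conf: Conformation, kind: str) -> None:
    if all(name == "CA" for name in conf.atom_names):
        raise UnsupportedTopologyError(
            f"{kind} detection needs an all-atom conformation (got CA-only)"
        )


def _residue_atoms(conf: Conformation) -> dict[int, list[int]]:
    by_res: dict[int, list[int]] = {}
    for k in range(conf.n_atoms):
        by_res.setdefault(int(conf.residue_indices[k]), []).append(k)
    return by_res


def _residue_names(conf: Conformation) -> dict[int, str]:
    return {
        int(conf.residue_indices[k]): conf.residue_names[k]
        for k in range(conf.n_atoms)
    }


def _closest_pair(
    conf: Conformation, atoms_i: list[int], atoms_j: list[int]
) -> tuple[float, int, int]:
    ci = conf.coords[atoms_i]
    cj = conf.coords[atoms_j]
    d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
    flat = int(np.argmin(d))
    a, b = divmod(flat, d.shape[1])
    return float(d[a, b]), atoms_i[a], atoms_j[b]


def detect_hbonds(
    conf: Conformation, cutoff: float = 3.5, min_angle: float = 120.0
) -> list[NoncovalentContact]:
    """Hydrogen bonds between residues by heavy-atom geometry.

    A donor heavy atom (N/O/S) within ``cutoff`` of an acceptor (N/O) on a
    residue >= 2 positions away counts; with explicit hydrogens bonded to the
    donor (within 1.3 A), at least one D-H...A angle must reach ``min_angle``
    degrees. One contact per residue pair (closest qualifying pair).
    """
    _require_all_atom(conf, "hydrogen-bond")
    donors_ok = {"N", "O", "S"}
    acceptors_ok = {"N", "O"}
    by_res = _residue_atoms(conf)
    hydrogens = [k for k in range(conf.n_atoms) if conf.elements[k] == "H"]
    contacts: list[NoncovalentContact] = []
    residues = sorted(by_res)
    for ri in residues:
        for rj in residues:
            if rj - ri < MIN_SEQ_SEPARATION:
                continue
            best: tuple[float, int, int] | None = None
            for a in by_res[ri]:
                for b in by_res[rj]:
                    ea, eb = conf.elements[a], conf.elements[b]
                    pair_ok = (ea in donors_ok and eb in acceptors_ok) or (
                        eb in donors_ok and ea in acceptors_ok
                    )
                    if not pair_ok:
                        continue
                    d = float(np.linalg.norm(conf.coords[a] - conf.coords[b]))
                    if d > cutoff:
                        continue
                    if hydrogens and not _angle_ok(conf, a, b, hydrogens, min_angle):
                        continue
                    if best is None or d < best[0]:
                        best = (d, a, b)
            if best is not None:
                d, a, b = best
                contacts.append(
                    NoncovalentContact(
                        kind="hbond",
                        residue_i=ri,
                        residue_j=rj,
                        atoms=(conf.atom_names[a], conf.atom_names[b]),
                        distance=d,
                        frame_index=conf.frame_index,
                    )
                )
    return contacts


def _angle_ok(
    conf: Conformation, donor: int, acceptor: int, hydrogens: list[int], min_angle: float
) -> bool:
    """True if some H bonded to either heavy atom gives D-H...A >= min_angle."""
    for d_atom, a_atom in ((donor, acceptor), (acceptor, donor)):
        for h in hydrogens:
            if np.linalg.norm(conf.coords[h] - conf.coords[d_atom]) > 1.3:
                continue
            v1 = conf.coords[d_atom] - conf.coords[h]
            v2 = conf.coords[a_atom] - conf.coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle >= min_angle:
                return True
    return False


def detect_hydrophobic(conf: Conformation, cutoff: float = 5.0) -> list[NoncovalentContact]:
    """Apolar side-chain carbon contacts, one per residue pair."""
    _require_all_atom(conf, "hydrophobic")
    by_res = _residue_atoms(conf)
    names = _residue_names(conf)
    contacts: list[NoncovalentContact] = []
    residues = sorted(by_res)
    for ri in residues:
        if names[ri] not in HYDROPHOBIC_RESIDUES:
            continue
        side_i = [
            k for k in by_res[ri]
            if conf.elements[k] == "C" and conf.atom_names[k] not in {"C", "CA"}
        ]
        if not side_i:
            continue
        for rj in residues:
            if rj - ri < MIN_SEQ_SEPARATION or names[rj] not in HYDROPHOBIC_RESIDUES:
                continue
            side_j = [
                k for k in by_res[rj]
                if conf.elements[k] == "C" and conf.atom_names[k] not in {"C", "CA"}
            ]
            if not side_j:
                continue
            d, a, b = _closest_pair(conf, side_i, side_j)
            if d <= cutoff:
                contacts.append(
                    NoncovalentContact(
                        kind="hydrophobic",
                        residue_i=ri,
                        residue_j=rj,
                        atoms=(conf.atom_names[a], conf.atom_names[b]),
                        distance=d,
                        frame_index=conf.frame_index,
                    )
                )
    return contacts


def detect_salt_bridges(conf: Conformation, cutoff: float = 4.0) -> list[NoncovalentContact]:
    """Basic-N to acidic-O contacts, one per residue pair."""
    _require_all_atom(conf, "salt-bridge")
    by_res = _residue_atoms(conf)
    names = _residue_names(conf)
    contacts: list[NoncovalentContact] = []
    residues = sorted(by_res)
    for ri in residues:
        for rj in residues:
            if rj - ri < MIN_SEQ_SEPARATION:
                continue
            for basic, acidic in ((ri, rj), (rj, ri)):
                bn = BASIC_ATOMS.get(names[basic])
                ao = ACIDIC_ATOMS.get(names[acidic])
                if not bn or not ao:
                    continue
                b_atoms = [k for k in by_res[basic] if conf.atom_names[k] in bn]
                a_atoms = [k for k in by_res[acidic] if conf.atom_names[k] in ao]
                if not b_atoms or not a_atoms:
                    continue
                d, a, b = _closest_pair(conf, b_atoms, a_atoms)
                if d <= cutoff:
                    contacts.append(
                        NoncovalentContact(
                            kind="salt_bridge",
                            residue_i=ri,
                            residue_j=rj,
                            atoms=(conf.atom_names[a], conf.atom_names[b]),
                            distance=d,
                            frame_index=conf.frame_index,
                        )
                    )
                    break  # one contact per residue pair
    return contacts


def detect_aromatic(conf: Conformation, cutoff: float = 7.0) -> list[NoncovalentContact]:
    """Ring-centroid contacts between aromatic residues (pi-pi proxy)."""
    _require_all_atom(conf, "aromatic")
    by_res = _residue_atoms(conf)
    names = _residue_names(conf)
    centroids: dict[int, np.ndarray] = {}
    for ri, atom_idx in by_res.items():
        ring = RING_ATOMS.get(names[ri])
        if ring is None:
            continue
        ring_atoms = [k for k in atom_idx if conf.atom_names[k] in ring]
        if len(ring_atoms) != len(ring):
            warnings.warn(
                f"residue {ri} ({names[ri]}): incomplete aromatic ring, skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        centroids[ri] = conf.coords[ring_atoms].mean(axis=0)
    contacts: list[NoncovalentContact] = []
    residues = sorted(centroids)
    for x, ri in enumerate(residues):
        for rj in residues[x + 1:]:
            if rj - ri < MIN_SEQ_SEPARATION:
                continue
            d = float(np.linalg.norm(centroids[ri] - centroids[rj]))
            if d <= cutoff:
                contacts.append(
                    NoncovalentContact(
                        kind="aromatic",
                        residue_i=ri,
                        residue_j=rj,
                        atoms=("ring", "ring"),
                        distance=d,
                        frame_index=conf.frame_index,
                    )
                )
    return contacts


_DETECTORS = {
    "hbond": detect_hbonds,
    "hydrophobic": detect_hydrophobic,
    "salt_bridge": detect_salt_bridges,
    "aromatic": detect_aromatic,
}


def detect_contacts(conf: Conformation, kind: str) -> list[NoncovalentContact]:
    try:
        return _DETECTORS[kind](conf)
    except KeyError:
        raise ValueError(f"unknown contact kind {kind!r}") from None


def interaction_time_series(ensemble: Ensemble, kind: str) -> InteractionSeries:
    """Per-frame residue-pair contact counts of one kind along the ensemble."""
    counts = [
        len(detect_contacts(ensemble.frame(f), kind)) for f in range(ensemble.n_frames)
    ]
    return InteractionSeries(kind=kind, counts=np.array(counts))


def aa_composition(sequence: str, selection: set[str] | None = None) -> dict[str, float]:
    """Percentage of each selected amino acid in a 1-letter sequence.

    Default selection is the stabilizing set K, R, E, F, Y, W.
    """
    if not sequence:
        raise ValueError("empty sequence")
    standard = set("ACDEFGHIKLMNPQRSTVWY")
    for pos, aa in enumerate(sequence):
        if aa not in standard:
            raise ValueError(f"non-standard amino acid {aa!r} at position {pos}")
    if selection is None:
        selection = set("KREFYW")
    return {
        aa: 100.0 * sequence.count(aa) / len(sequence) for aa in sorted(selection)
    }
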