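"""Conformational-ensemble containers and I/O.

An :class:`Ensemble` is an ordered stack of conformations (frames) over a
single fixed topology: the same atoms, in the same order, in every frame.
Everything downstream — RMSD series, PCA, cross-correlation matrices,
residue networks — assumes this contract, so it is enforced at read time.

Residues are indexed internally with a dense 0-based ``residue_index``;
author residue numbers (as printed in PDB files) are retained only for
reporting. Multi-model PDB files are read and written through biotite's
array-backed structure I/O; a plain-text coordinate-table dialect
(``frame,residue,x,y,z``, CA-only) is provided for small fixtures.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomRecord",
    "Conformation",
    "Ensemble",
    "ResidueAnnotation",
    "EnsembleError",
    "TopologyMismatchError",
    "PDBParseError",
    "FormatOverflowError",
    "SelectionError",
    "read_multimodel_pdb",
    "read_coord_table",
    "write_multimodel_pdb",
    "write_coord_table",
    "select_calpha",
    "read_pocket_annotation",
]


class EnsembleError(ValueError):
    """Base class for ensemble construction / I/O failures."""


class TopologyMismatchError(EnsembleError):
    """Models of one file (or frames of one ensemble) disagree on topology."""


class PDBParseError(EnsembleError):
    """An ATOM/HETATM record could not be parsed."""


class FormatOverflowError(EnsembleError):
    """A coordinate does not fit the fixed-column PDB field."""


class SelectionError(EnsembleError):
    """An atom selection is impossible on this topology."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology, with coordinates for one frame."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    author_residue_number: int
    coordinates: np.ndarray  # (3,) Angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise EnsembleError(
                f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector"
            )
        object.__setattr__(self, "coordinates", coords)


@dataclass
class Conformation:
    """A single frame: per-atom coordinates plus the shared topology.

    Array-backed; ``atoms`` materializes :class:`AtomRecord` objects on demand.
    """

    coords: np.ndarray  # (n_atoms, 3)
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    residue_indices: np.ndarray  # (n_atoms,) int, dense 0..R-1
    residue_names: tuple[str, ...]  # per atom
    chain_ids: tuple[str, ...]  # per atom
    author_residue_numbers: np.ndarray  # (n_atoms,) int
    frame_index: int = 0
    time_label: float | None = None  # ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.author_residue_numbers = np.asarray(self.author_residue_numbers, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise EnsembleError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise EnsembleError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max()) + 1 if self.n_atoms else 0

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=k + 1,
                name=self.atom_names[k],
                element=self.elements[k],
                residue_index=int(self.residue_indices[k]),
                residue_name=self.residue_names[k],
                chain_id=self.chain_ids[k],
                author_residue_number=int(self.author_residue_numbers[k]),
                coordinates=self.coords[k],
            )
            for k in range(self.n_atoms)
        ]

    def residue_sequence(self) -> list[str]:
        """Three-letter residue names in residue_index order."""
        seq: dict[int, str] = {}
        for k in range(self.n_atoms):
            seq.setdefault(int(self.residue_indices[k]), self.residue_names[k])
        return [seq[i] for i in range(len(seq))]

    def topology_key(self) -> tuple:
        return (
            self.atom_names,
            tuple(self.residue_indices.tolist()),
            tuple(self.residue_names),
        )


@dataclass
class Ensemble:
    """Stack of conformations sharing one topology.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)``; topology arrays are
    shared across frames. At least two frames are required before any
    correlation computation (enforced by the consumers, not here — a single
    frame is still a valid ensemble for e.g. writing).
    """

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    residue_indices: np.ndarray  # (n_atoms,)
    residue_names: tuple[str, ...]
    chain_ids: tuple[str, ...]
    author_residue_numbers: np.ndarray
    source: str = "unknown"
    time_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.author_residue_numbers = np.asarray(self.author_residue_numbers, dtype=int)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise EnsembleError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[0] == 0:
            raise EnsembleError("ensemble must contain at least one conformation")
        if not np.all(np.isfinite(self.coordinates)):
            raise EnsembleError("coordinates must be finite")
        n_atoms = self.coordinates.shape[1]
        for name, length in (
            ("atom_names", len(self.atom_names)),
            ("elements", len(self.elements)),
            ("residue_indices", len(self.residue_indices)),
            ("residue_names", len(self.residue_names)),
            ("chain_ids", len(self.chain_ids)),
            ("author_residue_numbers", len(self.author_residue_numbers)),
        ):
            if length != n_atoms:
                raise TopologyMismatchError(
                    f"{name} has length {length}, expected {n_atoms} atoms"
                )
        # residue_index must be dense 0..R-1
        uniq = np.unique(self.residue_indices)
        if uniq.size and not np.array_equal(uniq, np.arange(uniq.size)):
            raise EnsembleError("residue_index must be dense 0..R-1")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max()) + 1 if self.n_atoms else 0

    @property
    def topology_hash(self) -> str:
        digest = hashlib.sha256()
        digest.update("|".join(self.atom_names).encode())
        digest.update(b"#")
        digest.update(",".join(map(str, self.residue_indices.tolist())).encode())
        digest.update(b"#")
        digest.update("|".join(self.residue_names).encode())
        return digest.hexdigest()

    def frame(self, i: int) -> Conformation:
        return Conformation(
            coords=self.coordinates[i],
            atom_names=self.atom_names,
            elements=self.elements,
            residue_indices=self.residue_indices,
            residue_names=self.residue_names,
            chain_ids=self.chain_ids,
            author_residue_numbers=self.author_residue_numbers,
            frame_index=i,
            time_label=None if self.time_labels is None else float(self.time_labels[i]),
        )

    @property
    def conformations(self) -> list[Conformation]:
        return [self.frame(i) for i in range(self.n_frames)]

    def with_coordinates(self, coordinates: np.ndarray, source: str | None = None) -> "Ensemble":
        return replace(
            self,
            coordinates=np.asarray(coordinates, dtype=float),
            source=self.source if source is None else source,
        )

    def is_calpha_only(self) -> bool:
        return all(name == "CA" for name in self.atom_names)

    def residue_sequence(self) -> list[str]:
        return self.frame(0).residue_sequence()

    @staticmethod
    def from_conformations(
        conformations: list[Conformation], source: str = "unknown"
    ) -> "Ensemble":
        if not conformations:
            raise EnsembleError("cannot build an ensemble from zero conformations")
        first = conformations[0]
        key = first.topology_key()
        for conf in conformations[1:]:
            if conf.n_atoms != first.n_atoms:
                raise TopologyMismatchError(
                    f"frame {conf.frame_index} has {conf.n_atoms} atoms, "
                    f"expected {first.n_atoms}"
                )
            if conf.topology_key() != key:
                raise TopologyMismatchError(
                    f"frame {conf.frame_index} disagrees with frame 0 on topology"
                )
        coords = np.stack([c.coords for c in conformations])
        return Ensemble(
            coordinates=coords,
            atom_names=first.atom_names,
            elements=first.elements,
            residue_indices=first.residue_indices,
            residue_names=first.residue_names,
            chain_ids=first.chain_ids,
            author_residue_numbers=first.author_residue_numbers,
            source=source,
        )


@dataclass
class ResidueAnnotation:
    """Optional per-residue labels: catalytic pocket and free-form tags."""

    catalytic_pocket: frozenset[int] = frozenset()
    custom_labels: dict[int, str] = field(default_factory=dict)

    def validate(self, n_residues: int) -> None:
        bad = [i for i in self.catalytic_pocket if not 0 <= i < n_residues]
        bad += [i for i in self.custom_labels if not 0 <= i < n_residues]
        if bad:
            raise EnsembleError(
                f"annotation indices out of range for {n_residues} residues: {sorted(set(bad))}"
            )


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_ELEMENT_FROM_NAME = {"CA": "C", "CB": "C", "N": "N", "C": "C", "O": "O"}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name in _ELEMENT_FROM_NAME:
        return _ELEMENT_FROM_NAME[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def read_multimodel_pdb(path, chain: str | None = None) -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    One conformation per MODEL record (a file without MODEL records is a
    single implicit model). Only the first chain is kept unless ``chain``
    names another; for altlocs the highest-occupancy location wins (ties go
    to the first); insertion codes produce distinct residue indices.
    CA-only files are accepted.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises on malformed/ragged models
        msg = str(exc)
        if "same number of atoms" in msg or "atom count" in msg.lower():
            raise TopologyMismatchError(
                f"{path}: models disagree on atom count ({msg})"
            ) from exc
        raise PDBParseError(f"{path}: {msg}") from exc

    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])

    mask = struc.filter_amino_acids(stack[0])
    if not mask.any():
        mask = np.ones(stack.array_length(), dtype=bool)
    stack = stack[:, mask]

    chains = stack.chain_id[0] if stack.chain_id.ndim > 1 else stack.chain_id
    target_chain = chain if chain is not None else str(chains[0])
    chain_mask = chains == target_chain
    if not chain_mask.any():
        raise PDBParseError(f"{path}: chain {target_chain!r} not found")
    stack = stack[:, chain_mask]

    res_ids = stack.res_id
    ins = getattr(stack, "ins_code", np.full(stack.array_length(), ""))
    keys = list(zip(res_ids.tolist(), [str(x) for x in np.atleast_1d(ins)]))
    index_of: dict[tuple, int] = {}
    residue_indices = np.empty(len(keys), dtype=int)
    for k, key in enumerate(keys):
        if key not in index_of:
            index_of[key] = len(index_of)
        residue_indices[k] = index_of[key]

    elements = tuple(
        str(e) if str(e).strip() else _guess_element(str(n))
        for e, n in zip(stack.element, stack.atom_name)
    )
    return Ensemble(
        coordinates=np.asarray(stack.coord, dtype=float),
        atom_names=tuple(str(n) for n in stack.atom_name),
        elements=elements,
        residue_indices=residue_indices,
        residue_names=tuple(str(n) for n in stack.res_name),
        chain_ids=tuple(str(c) for c in stack.chain_id),
        author_residue_numbers=np.asarray(stack.res_id, dtype=int),
        source=f"pdb:{path}",
    )


def write_multimodel_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB file.

    Coordinates are rounded to 3 decimals (the fixed-column PDB resolution);
    any coordinate with magnitude >= 1e4 A cannot be represented and raises
    :class:`FormatOverflowError`.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if np.any(np.abs(ensemble.coordinates) >= 1e4):
        raise FormatOverflowError(
            "coordinate magnitude >= 10^4 A does not fit the PDB fixed-column format"
        )
    n_atoms = ensemble.n_atoms
    template = struc.AtomArray(n_atoms)
    template.coord = np.asarray(ensemble.coordinates[0], dtype=np.float32)
    template.atom_name = np.array(ensemble.atom_names)
    template.element = np.array(ensemble.elements)
    template.res_id = np.asarray(ensemble.author_residue_numbers)
    template.res_name = np.array(ensemble.residue_names)
    template.chain_id = np.array(ensemble.chain_ids)
    template.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.stack([template] * ensemble.n_frames)
    stack.coord = np.asarray(ensemble.coordinates, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    lines = list(pdb.lines)
    if not any(line.startswith("MODEL") for line in lines):
        # single-frame stacks are still written as an explicit MODEL/ENDMDL pair
        lines = ["MODEL        1"] + lines + ["ENDMDL"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Fixture coordinate-table dialect: header `frame,residue,x,y,z`, CA-only
# ---------------------------------------------------------------------------


def read_coord_table(path) -> Ensemble:
    """Read the CA-only fixture dialect (CSV: ``frame,residue,x,y,z``)."""
    import pandas as pd

    df = pd.read_csv(path)
    expected = ["frame", "residue", "x", "y", "z"]
    if list(df.columns) != expected:
        raise PDBParseError(
            f"{path}: expected header {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    if df.duplicated(subset=["frame", "residue"]).any():
        dup = df[df.duplicated(subset=["frame", "residue"])].iloc[0]
        raise PDBParseError(
            f"{path}: duplicate (frame,residue) row ({int(dup['frame'])},{int(dup['residue'])})"
        )
    frames = np.sort(df["frame"].unique())
    residues = np.sort(df["residue"].unique())
    n_frames, n_res = len(frames), len(residues)
    if not np.array_equal(frames, np.arange(n_frames)):
        raise PDBParseError(f"{path}: frame ids must be dense 0..{n_frames - 1}")
    if not np.array_equal(residues, np.arange(n_res)):
        raise PDBParseError(f"{path}: residue ids must be dense 0..{n_res - 1}")
    if len(df) != n_frames * n_res:
        raise PDBParseError(
            f"{path}: missing rows — expected {n_frames * n_res}, got {len(df)}"
        )
    df = df.sort_values(["frame", "residue"], kind="mergesort")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(n_frames, n_res, 3)
    return Ensemble(
        coordinates=coords,
        atom_names=("CA",) * n_res,
        elements=("C",) * n_res,
        residue_indices=np.arange(n_res),
        residue_names=("ALA",) * n_res,
        chain_ids=("A",) * n_res,
        author_residue_numbers=np.arange(1, n_res + 1),
        source=f"coord_table:{path}",
    )


def write_coord_table(ensemble: Ensemble, path) -> None:
    """Write a CA-only ensemble in the fixture CSV dialect."""
    if not ensemble.is_calpha_only():
        raise SelectionError("coordinate tables are CA-only; call select_calpha first")
    buf = io.StringIO()
    buf.write("frame,residue,x,y,z\n")
    for f in range(ensemble.n_frames):
        for r in range(ensemble.n_atoms):
            x, y, z = ensemble.coordinates[f, r]
            buf.write(f"{f},{r},{x:.6f},{y:.6f},{z:.6f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def select_calpha(ensemble: Ensemble) -> Ensemble:
    """Reduce an ensemble to its CA atoms, one per residue, order preserved.

    Idempotent on CA-only input. A residue lacking a CA atom is a contract
    violation and raises :class:`SelectionError` naming the residue.
    """
    if ensemble.is_calpha_only():
        return ensemble
    mask = np.array([name == "CA" for name in ensemble.atom_names])
    seen = ensemble.residue_indices[mask]
    all_res = np.unique(ensemble.residue_indices)
    missing = sorted(set(all_res.tolist()) - set(seen.tolist()))
    if missing:
        names = {int(ensemble.residue_indices[k]): ensemble.residue_names[k]
                 for k in range(ensemble.n_atoms)}
        first = missing[0]
        raise SelectionError(
            f"residue {first} ({names.get(first, '?')}) has no CA atom"
        )
    dup = len(seen) != len(np.unique(seen))
    if dup:
        raise SelectionError("a residue has more than one CA atom")
    idx = np.where(mask)[0]
    return Ensemble(
        coordinates=ensemble.coordinates[:, idx, :],
        atom_names=tuple(ensemble.atom_names[k] for k in idx),
        elements=tuple(ensemble.elements[k] for k in idx),
        residue_indices=ensemble.residue_indices[idx],
        residue_names=tuple(ensemble.residue_names[k] for k in idx),
        chain_ids=tuple(ensemble.chain_ids[k] for k in idx),
        author_residue_numbers=ensemble.author_residue_numbers[idx],
        source=ensemble.source,
        time_labels=ensemble.time_labels,
    )


def read_pocket_annotation(path) -> ResidueAnnotation:
    """Read a catalytic-pocket file: one 0-based residue index per line."""
    indices = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            try:
                indices.add(int(line))
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}:{lineno}: expected an integer residue index, got {line!r}"
                ) from exc
    return ResidueAnnotation(catalytic_pocket=frozenset(indices))
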