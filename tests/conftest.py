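import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dscls.ensemble_io import Conformation, Ensemble


def make_conformation(residues, frame_index=0):
    """Build an all-atom conformation from a residue description list.

    ``residues``: list of (res_name, [(atom_name, element, (x, y, z)), ...]).
    """
    atom_names, elements, res_idx, res_names, coords = [], [], [], [], []
    for ri, (rname, atoms) in enumerate(residues):
        for aname, elem, xyz in atoms:
            atom_names.append(aname)
            elements.append(elem)
            res_idx.append(ri)
            res_names.append(rname)
            coords.append(xyz)
    n = len(atom_names)
    return Conformation(
        coords=np.array(coords, dtype=float),
        atom_names=tuple(atom_names),
        elements=tuple(elements),
        residue_indices=np.array(res_idx),
        residue_names=tuple(res_names),
        chain_ids=("A",) * n,
        author_residue_numbers=np.array(res_idx) + 1,
        frame_index=frame_index,
    )


def ca_ensemble(coords, source="test"):
    """CA-only ensemble from a (F, R, 3) array."""
    coords = np.asarray(coords, dtype=float)
    _, R, _ = coords.shape
    return Ensemble(
        coordinates=coords,
        atom_names=("CA",) * R,
        elements=("C",) * R,
        residue_indices=np.arange(R),
        residue_names=("ALA",) * R,
        chain_ids=("A",) * R,
        author_residue_numbers=np.arange(1, R + 1),
        source=source,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tripeptide_pdb(tmp_path):
    """Two-model PDB of a 3-residue CA+N peptide."""
    lines = []
    for model in (1, 2):
        lines.append(f"MODEL     {model:4d}")
        serial = 1
        for ri, rname in enumerate(["ALA", "GLY", "SER"], start=1):
            for aname, elem, dx in (("N", "N", -0.7), ("CA", "C", 0.0)):
                x = 3.8 * (ri - 1) + dx + 0.1 * (model - 1)
                lines.append(
                    f"ATOM  {serial:5d} {aname:^4s}{rname:>4s} A{ri:4d}    "
                    f"{x:8.3f}{1.0:8.3f}{2.0:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {elem:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "tri.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
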