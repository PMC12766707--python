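import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import ca_ensemble, make_conformation
from dscls.ensemble_io import Ensemble
from dscls.interactions import (
    RING_ATOMS,
    UnsupportedTopologyError,
    aa_composition,
    detect_aromatic,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
    interaction_time_series,
)


def _res(name, atoms):
    return (name, atoms)


def _spacer(x):
    """A glycine far from everything, to pad sequence separation."""
    return _res("GLY", [("N", "N", (x, 50, 50)), ("CA", "C", (x + 1, 50, 50))])


class TestHbondCutoff:
    def _pair(self, d):
        return make_conformation([
            _res("SER", [("CA", "C", (0, 0, 0)), ("OG", "O", (1, 0, 0))]),
            _spacer(100),
            _res("THR", [("CA", "C", (1 + d, 3, 0)), ("OG1", "O", (1 + d, 0, 0))]),
        ])

    def test_inside_cutoff_detected(self):
        contacts = detect_hbonds(self._pair(3.4))
        assert len(contacts) == 1
        assert (contacts[0].residue_i, contacts[0].residue_j) == (0, 2)
        assert contacts[0].distance == pytest.approx(3.4)

    def test_outside_cutoff_rejected(self):
        assert detect_hbonds(self._pair(3.6)) == []

    def test_ca_only_unsupported(self):
        conf = ca_ensemble(np.zeros((1, 3, 3))).frame(0)
        with pytest.raises(UnsupportedTopologyError):
            detect_hbonds(conf)

    def test_angle_filter_with_explicit_hydrogens(self):
        # donor O-H pointing away from the acceptor: angle ~0 deg, rejected
        conf = make_conformation([
            _res("SER", [("CA", "C", (0, 0, 0)), ("OG", "O", (1, 0, 0)),
                         ("HG", "H", (0.2, 0, 0))]),
            _spacer(100),
            _res("THR", [("CA", "C", (4.0, 3, 0)), ("OG1", "O", (4.0, 0, 0))]),
        ])
        assert detect_hbonds(conf) == []
        # O-H pointing toward the acceptor passes
        conf2 = make_conformation([
            _res("SER", [("CA", "C", (0, 0, 0)), ("OG", "O", (1, 0, 0)),
                         ("HG", "H", (1.9, 0, 0))]),
            _spacer(100),
            _res("THR", [("CA", "C", (4.0, 3, 0)), ("OG1", "O", (4.0, 0, 0))]),
        ])
        assert len(detect_hbonds(conf2)) == 1


class TestHydrophobicCutoff:
    def _leucines(self, d):
        return make_conformation([
            _res("LEU", [("CA", "C", (0, 0, 0)), ("CD1", "C", (1, 0, 0))]),
            _spacer(100),
            _res("LEU", [("CA", "C", (1 + d + 1, 0, 0)), ("CD1", "C", (1 + d, 0, 0))]),
        ])

    def test_inside_cutoff(self):
        contacts = detect_hydrophobic(self._leucines(4.5))
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.5)

    def test_outside_cutoff(self):
        assert detect_hydrophobic(self._leucines(5.5)) == []

    def test_backbone_carbons_ignored(self):
        # only CA/C atoms close: no side-chain carbon pair exists
        conf = make_conformation([
            _res("LEU", [("CA", "C", (0, 0, 0)), ("C", "C", (1, 0, 0))]),
            _spacer(100),
            _res("LEU", [("CA", "C", (3, 0, 0)), ("C", "C", (2, 0, 0))]),
        ])
        assert detect_hydrophobic(conf) == []


class TestSaltBridgeCutoff:
    def _arg_glu(self, d):
        return make_conformation([
            _res("ARG", [("CA", "C", (0, 0, 0)), ("NH1", "N", (1, 0, 0))]),
            _spacer(100),
            _res("GLU", [("CA", "C", (1 + d, 2, 0)), ("OE1", "O", (1 + d, 0, 0))]),
        ])

    def test_inside_cutoff(self):
        contacts = detect_salt_bridges(self._arg_glu(3.8))
        assert len(contacts) == 1
        assert contacts[0].atoms == ("NH1", "OE1")

    def test_outside_cutoff(self):
        assert detect_salt_bridges(self._arg_glu(4.2)) == []

    def test_nonionic_pairs_ignored(self):
        conf = make_conformation([
            _res("SER", [("CA", "C", (0, 0, 0)), ("OG", "O", (1, 0, 0))]),
            _spacer(100),
            _res("THR", [("CA", "C", (4, 2, 0)), ("OG1", "O", (4, 0, 0))]),
        ])
        assert detect_salt_bridges(conf) == []


class TestAromatic:
    def _phe_ring(self, center, rname="PHE"):
        ring = RING_ATOMS[rname]
        atoms = [("CA", "C", (center[0], center[1] + 5, center[2]))]
        for k, name in enumerate(ring):
            ang = 2 * np.pi * k / len(ring)
            atoms.append(
                (name, "C", (center[0] + 1.4 * np.cos(ang),
                             center[1] + 1.4 * np.sin(ang), center[2]))
            )
        return _res(rname, atoms)

    def test_inside_cutoff(self):
        conf = make_conformation([
            self._phe_ring((0, 0, 0)), _spacer(100), self._phe_ring((6, 0, 0)),
        ])
        contacts = detect_aromatic(conf)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(6.0, abs=1e-10)

    def test_outside_cutoff(self):
        conf = make_conformation([
            self._phe_ring((0, 0, 0)), _spacer(100), self._phe_ring((7.5, 0, 0)),
        ])
        assert detect_aromatic(conf) == []

    def test_centroid_equals_ring_atom_mean(self):
        conf = make_conformation([
            self._phe_ring((0, 0, 0)), _spacer(100), self._phe_ring((6.5, 0.3, 0.2)),
        ])
        contacts = detect_aromatic(conf)
        ring = RING_ATOMS["PHE"]
        c1 = np.mean([conf.coords[k] for k in range(conf.n_atoms)
                      if conf.residue_indices[k] == 0 and conf.atom_names[k] in ring], axis=0)
        c2 = np.mean([conf.coords[k] for k in range(conf.n_atoms)
                      if conf.residue_indices[k] == 2 and conf.atom_names[k] in ring], axis=0)
        assert contacts[0].distance == pytest.approx(float(np.linalg.norm(c1 - c2)), abs=1e-10)

    def test_incomplete_ring_skipped_with_warning(self):
        broken = _res("PHE", [("CA", "C", (0, 5, 0)), ("CG", "C", (0, 0, 0))])
        conf = make_conformation([broken, _spacer(100), self._phe_ring((6, 0, 0))])
        with pytest.warns(RuntimeWarning, match="incomplete"):
            assert detect_aromatic(conf) == []


def five_residue_fixture(frame_shift=0.0):
    """All-atom 5-residue fixture exercising every detector at once."""
    return make_conformation([
        _res("LEU", [("CA", "C", (0, 0, 0)), ("CD1", "C", (1, 0, 0))]),
        _res("ARG", [("CA", "C", (4, 4, 0)), ("NH1", "N", (5, 4, 0))]),
        _res("ILE", [("CA", "C", (4.5 + frame_shift, 0, 0)),
                     ("CD1", "C", (4.0 + frame_shift, 0, 0))]),
        _res("GLU", [("CA", "C", (5, 8, 0)), ("OE1", "O", (5, 7.5, 0))]),
        _res("SER", [("CA", "C", (0, 4, 0)), ("OG", "O", (0.5, 4, 0))]),
    ])


class TestBruteForceOracle:
    @pytest.mark.parametrize("kind,detector,cutoff", [
        ("hbond", detect_hbonds, 3.5),
        ("hydrophobic", detect_hydrophobic, 5.0),
        ("salt_bridge", detect_salt_bridges, 4.0),
    ])
    def test_detector_matches_exhaustive_scan(self, kind, detector, cutoff):
        from dscls.interactions import ACIDIC_ATOMS, BASIC_ATOMS, HYDROPHOBIC_RESIDUES

        conf = five_residue_fixture()
        found = {(c.residue_i, c.residue_j) for c in detector(conf)}
        expected = set()
        for a in range(conf.n_atoms):
            for b in range(conf.n_atoms):
                ri, rj = int(conf.residue_indices[a]), int(conf.residue_indices[b])
                if rj - ri < 2:
                    continue
                d = np.linalg.norm(conf.coords[a] - conf.coords[b])
                if d > cutoff:
                    continue
                na, nb = conf.residue_names[a], conf.residue_names[b]
                ea, eb = conf.elements[a], conf.elements[b]
                ana, anb = conf.atom_names[a], conf.atom_names[b]
                if kind == "hbond":
                    ok = (ea in "NOS" and eb in "NO") or (eb in "NOS" and ea in "NO")
                elif kind == "hydrophobic":
                    ok = (
                        na in HYDROPHOBIC_RESIDUES and nb in HYDROPHOBIC_RESIDUES
                        and ea == eb == "C" and ana not in ("C", "CA")
                        and anb not in ("C", "CA")
                    )
                else:
                    ok = (
                        ana in BASIC_ATOMS.get(na, ()) and anb in ACIDIC_ATOMS.get(nb, ())
                    ) or (
                        anb in BASIC_ATOMS.get(nb, ()) and ana in ACIDIC_ATOMS.get(na, ())
                    )
                if ok:
                    expected.add((ri, rj))
        assert found == expected

    def test_rigid_transform_invariance(self, rng):
        conf = five_residue_fixture()
        rot = Rotation.random(random_state=rng).as_matrix()
        coords = conf.coords @ rot.T + rng.normal(size=3) * 30
        import dataclasses

        moved = dataclasses.replace(conf, coords=coords)
        for det in (detect_hbonds, detect_hydrophobic, detect_salt_bridges):
            a = [(c.residue_i, c.residue_j, round(c.distance, 9)) for c in det(conf)]
            b = [(c.residue_i, c.residue_j, round(c.distance, 9)) for c in det(moved)]
            assert a == b


class TestTimeSeries:
    def _ensemble(self):
        frames = [five_residue_fixture(0.0), five_residue_fixture(0.0),
                  five_residue_fixture(50.0)]
        confs = []
        for k, f in enumerate(frames):
            import dataclasses

            confs.append(dataclasses.replace(f, frame_index=k))
        return Ensemble.from_conformations(confs)

    def test_static_ensemble_constant_series(self):
        import dataclasses

        conf = five_residue_fixture()
        ens = Ensemble.from_conformations(
            [dataclasses.replace(conf, frame_index=k) for k in range(3)]
        )
        series = interaction_time_series(ens, "hydrophobic")
        assert len(set(series.counts.tolist())) == 1

    def test_separating_a_pair_drops_count_by_one(self):
        ens = self._ensemble()
        series = interaction_time_series(ens, "hydrophobic")
        assert series.counts[0] == series.counts[1] == series.counts[2] + 1

    def test_series_conserves_detector_totals(self):
        from dscls.interactions import detect_contacts

        ens = self._ensemble()
        for kind in ("hbond", "hydrophobic", "salt_bridge"):
            series = interaction_time_series(ens, kind)
            total = sum(len(detect_contacts(ens.frame(f), kind)) for f in range(3))
            assert series.counts.sum() == total


class TestComposition:
    def test_simple_fractions(self):
        assert aa_composition("KKRR", {"K", "R"}) == {"K": 50.0, "R": 50.0}

    def test_absent_selection_is_zero(self):
        out = aa_composition("AAAA", {"W"})
        assert out == {"W": 0.0}

    def test_random_sequence_matches_direct_count(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        out = aa_composition(seq)
        for aa, pct in out.items():
            assert pct == pytest.approx(100 * seq.count(aa) / 200, abs=1e-12)
        assert set(out) == set("KREFYW")

    def test_nonstandard_letter_position_reported(self):
        with pytest.raises(ValueError, match="position 2"):
            aa_composition("AAXA")
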