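import numpy as np
import pytest

from cglamella import mapping as mp
from cglamella import topology as topo
from cglamella.frames import AtomisticFrame, CGFrame


def chain_template(n_carbons: int) -> topo.MoleculeTemplate:
    """A bare alkyl chain template (no hydrogens) for mapping geometry tests."""
    beads = topo.tail_bead_sequence(n_carbons, 0)
    formulas = [{"C": 3 if b == "TAIL" else 2} for b in beads]
    atoms, groups, i = [], [], 0
    for f in formulas:
        grp = [topo.AtomSpec(f"C{i + j + 1}", "C") for j in range(f["C"])]
        i += f["C"]
        groups.append(grp)
    idx = list(range(len(beads)))
    return topo.MoleculeTemplate(
        name="ALKANE",
        beads=beads,
        bead_formulas=formulas,
        atom_groups=groups,
        bonds=[(a, a + 1) for a in idx[:-1]],
        angles=[(a, a + 1, a + 2) for a in idx[:-2]],
    )


def atomistic_from_template(t, positions, box=(10, 10, 10), resid=1):
    names = [a.name for grp in t.atom_groups for a in grp]
    masses = [a.mass for grp in t.atom_groups for a in grp]
    return AtomisticFrame(
        positions=np.asarray(positions, dtype=float),
        masses=np.array(masses),
        names=np.array(names),
        resids=np.full(len(names), resid),
        resnames=np.array(["MOL"] * len(names)),
        box=np.array(box, dtype=float),
    )


class TestMapFrame:
    def test_degenerate_all_atoms_at_origin(self, registry):
        t = registry["CER_NS"]
        n_atoms = sum(len(g) for g in t.atom_groups)
        frame = AtomisticFrame(
            positions=np.full((n_atoms, 3), 5.0),
            masses=np.array([a.mass for g in t.atom_groups for a in g]),
            names=np.array([a.name for g in t.atom_groups for a in g]),
            resids=np.ones(n_atoms, dtype=int),
            resnames=np.array(["CER"] * n_atoms),
            box=np.array([10.0, 10.0, 10.0]),
        )
        cg = mp.map_frame(frame, registry, {"CER": "CER_NS"})
        assert cg.n_beads == t.n_beads
        assert np.allclose(cg.positions, 5.0)

    def test_equal_mass_pair_maps_to_midpoint(self):
        t = chain_template(2)  # single TER2 bead of two carbons
        frame = atomistic_from_template(t, [[0, 0, 0], [0, 0, 1.0]])
        cg = mp.map_frame(frame, {"ALKANE": t}, {"MOL": "ALKANE"})
        assert cg.positions[0] == pytest.approx([0, 0, 0.5])

    def test_all_trans_chain_beads_equally_spaced(self):
        """18 carbons at 0.127 nm z-rise -> 6 TAIL beads spaced 0.381 nm.

        Closed form: bead j covers carbons 3j..3j+2, so its centre is at
        z = 0.127 (3j + 1)."""
        t = chain_template(18)
        pos = [[0, 0, 0.127 * i] for i in range(18)]
        frame = atomistic_from_template(t, pos)
        cg = mp.map_frame(frame, {"ALKANE": t}, {"MOL": "ALKANE"})
        expected = 0.127 * (3 * np.arange(6) + 1)
        assert cg.positions[:, 2] == pytest.approx(expected)
        assert np.diff(cg.positions[:, 2]) == pytest.approx([0.381] * 5)

    def test_mass_and_com_conserved(self, registry):
        t = registry["CER_NP"]
        rng = np.random.default_rng(11)
        n_atoms = sum(len(g) for g in t.atom_groups)
        pos = rng.uniform(2.0, 4.0, size=(n_atoms, 3))  # whole molecule
        masses = np.array([a.mass for g in t.atom_groups for a in g])
        frame = AtomisticFrame(
            positions=pos,
            masses=masses,
            names=np.array([a.name for g in t.atom_groups for a in g]),
            resids=np.ones(n_atoms, dtype=int),
            resnames=np.array(["CER"] * n_atoms),
            box=np.array([10.0, 10.0, 10.0]),
        )
        cg = mp.map_frame(frame, registry, {"CER": "CER_NP"})
        assert cg.masses.sum() == pytest.approx(masses.sum(), abs=1e-9)
        com_aa = np.average(pos, axis=0, weights=masses)
        com_cg = np.average(cg.positions, axis=0, weights=cg.masses)
        assert com_cg == pytest.approx(com_aa, abs=1e-9)

    def test_permutation_invariant_to_atom_order(self):
        t = chain_template(6)
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 2, size=(6, 3))
        f1 = atomistic_from_template(t, pos)
        perm = rng.permutation(6)
        f2 = AtomisticFrame(
            positions=f1.positions[perm],
            masses=f1.masses[perm],
            names=f1.names[perm],
            resids=f1.resids[perm],
            resnames=f1.resnames[perm],
            box=f1.box,
        )
        cg1 = mp.map_frame(f1, {"ALKANE": t}, {"MOL": "ALKANE"})
        cg2 = mp.map_frame(f2, {"ALKANE": t}, {"MOL": "ALKANE"})
        assert np.allclose(cg1.positions, cg2.positions)

    def test_missing_atom_named_in_error(self):
        t = chain_template(6)
        frame = atomistic_from_template(t, np.zeros((6, 3)))
        frame.names[2] = "XX"
        with pytest.raises(mp.MappingError, match="C3"):
            mp.map_frame(frame, {"ALKANE": t}, {"MOL": "ALKANE"})

    def test_broken_molecule_requires_unwrap(self):
        t = chain_template(2)
        pos = [[0, 0, 0.1], [0, 0, 9.9]]  # wrapped across z in a 10 nm box
        frame = atomistic_from_template(t, pos)
        with pytest.raises(mp.MappingError, match="unwrap"):
            mp.map_frame(frame, {"ALKANE": t}, {"MOL": "ALKANE"})
        cg = mp.map_frame(frame, {"ALKANE": t}, {"MOL": "ALKANE"}, unwrap=True)
        assert cg.positions[0, 2] == pytest.approx(0.0, abs=1e-9)


class TestMapWater:
    def test_square_corners_map_to_centre(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        beads, short = mp.map_water(pos, ratio=4)
        assert beads.shape == (1, 3)
        assert beads[0] == pytest.approx([0.5, 0.5, 0.0])
        assert not short.any()

    def test_two_tight_clusters_resolved(self):
        rng = np.random.default_rng(0)
        a = rng.normal([1, 1, 1], 0.05, size=(4, 3))
        b = rng.normal([8, 8, 8], 0.05, size=(4, 3))
        pos = np.vstack([a, b])[rng.permutation(8)]
        beads, short = mp.map_water(pos, ratio=4)
        assert beads.shape == (2, 3)
        centres = sorted(beads[:, 0])
        assert centres[0] == pytest.approx(a[:, 0].mean(), abs=0.2)
        assert centres[1] == pytest.approx(b[:, 0].mean(), abs=0.2)

    def test_empty_input(self):
        beads, short = mp.map_water(np.empty((0, 3)))
        assert beads.shape == (0, 3)

    def test_remainder_cluster_flagged(self):
        beads, short = mp.map_water(np.random.default_rng(1).random((7, 3)))
        assert len(beads) == 2
        assert short.sum() == 1


class TestBondedSamples:
    def frame_two_beads(self, z2, box_z=5.0):
        return CGFrame(
            positions=np.array([[1.0, 1.0, 0.1], [1.0, 1.0, z2]]),
            bead_types=np.array(["TAIL", "TER2"]),
            mol_ids=np.array([0, 0]),
            mol_species=np.array(["ALKANE", "ALKANE"]),
            box=np.array([5.0, 5.0, box_z]),
        )

    def test_fixed_bond_length_in_angstrom(self):
        t = chain_template(5)  # TAIL + TER2
        frames = [self.frame_two_beads(0.1 + 0.24) for _ in range(3)]
        out = mp.bonded_samples(frames, t)
        assert set(out) == {"TAIL-TER2"}
        assert out["TAIL-TER2"].kind == "bond"
        assert out["TAIL-TER2"].values == pytest.approx([2.4] * 3)

    def test_minimum_image_across_boundary(self):
        t = chain_template(5)
        out = mp.bonded_samples([self.frame_two_beads(4.9)], t)
        # 0.1 and 4.9 nm in a 5 nm box are 0.2 nm (2 Å) apart, not 4.8 nm
        assert out["TAIL-TER2"].values == pytest.approx([2.0])

    def test_collinear_angle_is_180(self):
        t = chain_template(8)  # 2 TAIL + TER2, one angle
        frame = CGFrame(
            positions=np.array([[1, 1, 1.0], [1, 1, 1.4], [1, 1, 1.8]]),
            bead_types=np.array(["TAIL", "TAIL", "TER2"]),
            mol_ids=np.zeros(3, dtype=int),
            mol_species=np.array(["ALKANE"] * 3),
            box=np.array([5.0, 5.0, 5.0]),
        )
        out = mp.bonded_samples([frame], t)
        assert out["TAIL-TAIL-TER2"].values == pytest.approx([180.0])

    def test_empty_selection_errors(self, registry):
        frame = self.frame_two_beads(0.3)
        with pytest.raises(mp.MappingError, match="CER_NS"):
            mp.bonded_samples([frame], registry["CER_NS"])
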