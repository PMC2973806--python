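import numpy as np
import pytest

import catnets as cn

from .conftest_helpers import structure_from_sequence
from .oracles import cmi_brute, proximity_brute


class TestReadStructure:
    def test_standard_residues_only(self, toy_pdb):
        s = cn.read_structure(toy_pdb, chain="A")
        assert len(s) == 3  # water dropped
        assert s.one_letter_sequence() == "ACD"

    def test_first_model_selected(self, toy_pdb):
        s = cn.read_structure(toy_pdb, chain="A", model=1)
        assert s.residues[0].coords[0, 0] < 10  # model 2 sits at 50+

    def test_second_model_accessible(self, toy_pdb):
        s = cn.read_structure(toy_pdb, chain="A", model=2)
        assert s.residues[0].coords[0, 0] == pytest.approx(50.0)

    def test_hydrogens_excluded(self, toy_pdb):
        s = cn.read_structure(toy_pdb, chain="A")
        assert len(s.residues[0].coords) == 2  # N + CA, H dropped

    def test_missing_chain_lists_available(self, toy_pdb):
        with pytest.raises(ValueError, match="available chains"):
            cn.read_structure(toy_pdb, chain="Z")

    def test_other_chain(self, toy_pdb):
        assert cn.read_structure(toy_pdb, chain="B").one_letter_sequence() == "G"


class TestDistanceMatrix:
    def test_three_four_five(self):
        from .conftest import make_structure

        s = make_structure([[0, 0, 0], [3, 4, 0]])
        dm = cn.residue_distance_matrix(s)
        assert dm.distances[0, 1] == pytest.approx(5.0)
        assert dm.distances[1, 0] == pytest.approx(5.0)
        assert dm.distances[0, 0] == 0.0

    def test_minimum_not_centroid(self):
        # closest atoms at 2 A although the residue centers sit 8 A apart
        r1 = cn.Residue("A", 1, " ", "ALA", np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        r2 = cn.Residue("A", 2, " ", "ALA", np.array([[5.0, 0, 0], [8.0, 0, 0]]))
        dm = cn.residue_distance_matrix(cn.Structure([r1, r2]))
        assert dm.distances[0, 1] == pytest.approx(2.0)

    def test_hydrogens_never_enter(self, toy_pdb):
        s = cn.read_structure(toy_pdb, chain="A")
        dm = cn.residue_distance_matrix(s)
        # residue 1's H atom at (9,9,9) would be ~1.4 A from nothing real;
        # the N/CA-only distance to residue 2 is the 3-4-5-ish value below
        assert dm.distances[0, 1] == pytest.approx(np.sqrt(4 + 16))


def fake_mi(apc, z):
    apc = np.asarray(apc, dtype=float)
    z = np.asarray(z, dtype=float)
    np.fill_diagonal(apc, np.nan)
    np.fill_diagonal(z, np.nan)
    return cn.MIResult(mi_raw=np.abs(apc), mi_apc=apc, zscores=z, n_permutations=20, seed=0)


class TestCumulativeMI:
    def test_nothing_passes(self):
        mi = fake_mi(np.ones((3, 3)), np.ones((3, 3)))
        assert np.allclose(cn.cumulative_mi(mi, z_threshold=5.0), 0.0)

    def test_single_edge(self):
        apc = np.zeros((4, 4))
        z = np.zeros((4, 4))
        apc[1, 2] = apc[2, 1] = 0.8
        z[1, 2] = z[2, 1] = 7.0
        out = cn.cumulative_mi(fake_mi(apc, z), z_threshold=6.0)
        assert np.allclose(out, [0.0, 0.8, 0.8, 0.0])

    def test_clique_matches_brute_force(self):
        rng = np.random.default_rng(4)
        apc = rng.random((6, 6))
        apc = (apc + apc.T) / 2
        z = rng.uniform(0, 12, size=(6, 6))
        z = (z + z.T) / 2
        mi = fake_mi(apc.copy(), z.copy())
        out = cn.cumulative_mi(mi, z_threshold=6.0)
        expected = cmi_brute(np.nan_to_num(mi.mi_apc).tolist(), np.nan_to_num(mi.zscores, nan=-99).tolist(), 6.0)
        assert np.allclose(out, expected, atol=1e-9)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        apc = np.abs(rng.random((8, 8)))
        apc = (apc + apc.T) / 2
        z = rng.uniform(0, 10, (8, 8))
        z = (z + z.T) / 2
        mi = fake_mi(apc, z)
        values = [cn.cumulative_mi(mi, t).sum() for t in (2.0, 4.0, 6.0, 8.0)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestProximityAverage:
    def make_dm(self, coords):
        from .conftest import make_structure

        return cn.residue_distance_matrix(make_structure(coords))

    def test_plain_mean_of_neighbors(self):
        dm = self.make_dm([[0, 0, 0], [3, 0, 0], [0, 3, 0], [50, 50, 50]])
        values = np.array([0.0, 2.0, 4.0, 9.0])
        avg = cn.proximity_average(values, dm, 5.0, normalize=False)
        assert avg[0] == pytest.approx(3.0)  # mean of {2, 4}
        assert avg[3] == 0.0  # isolated

    def test_constant_input_degenerates_to_zero(self):
        dm = self.make_dm([[0, 0, 0], [3, 0, 0], [6, 0, 0]])
        assert np.allclose(cn.proximity_average(np.full(3, 5.0), dm, 4.0), 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 15, size=(5, 3))
        dm = self.make_dm(coords)
        values = rng.random(5) * 10
        out = cn.proximity_average(values, dm, 7.5)
        expected = proximity_brute(values.tolist(), dm.distances.tolist(), 7.5)
        assert np.allclose(out, expected, atol=1e-9)

    def test_output_in_unit_interval_and_affine_invariant(self):
        rng = np.random.default_rng(2)
        dm = self.make_dm(rng.uniform(0, 20, size=(10, 3)))
        values = rng.random(10)
        out = cn.proximity_average(values, dm, 8.0)
        assert np.all((out >= 0) & (out <= 1))
        scaled = cn.proximity_average(3.5 * values + 2.0, dm, 8.0)
        assert np.allclose(out, scaled)

    def test_infinite_threshold_collapses(self):
        # with the residue itself included, an infinite neighborhood gives
        # every residue the same (global) mean -> degenerate rescale to 0
        rng = np.random.default_rng(3)
        dm = self.make_dm(rng.uniform(0, 10, size=(6, 3)))
        out = cn.proximity_average(rng.random(6), dm, 1e9, include_self=True)
        assert np.allclose(out, 0.0)

    def test_include_self_changes_average(self):
        dm = self.make_dm([[0, 0, 0], [3, 0, 0]])
        values = np.array([0.0, 10.0])
        without = cn.proximity_average(values, dm, 5.0, normalize=False)
        with_self = cn.proximity_average(values, dm, 5.0, include_self=True, normalize=False)
        assert without[0] == pytest.approx(10.0)
        assert with_self[0] == pytest.approx(5.0)


def test_bfactor_score_coloring(tmp_path):
    s = structure_from_sequence("ACD")
    scores = {("A", 1, " "): 1.25, ("A", 2, " "): 0.5, ("A", 3, " "): 2.0}
    path = tmp_path / "colored.pdb"
    cn.write_structure(s, path, bfactors=scores)
    b = [
        float(line[60:66])
        for line in path.read_text().splitlines()
        if line.startswith("ATOM")
    ]
    assert b == [1.25, 0.5, 2.0]


def test_structure_roundtrip(tmp_path):
    s = structure_from_sequence("ACDEFG")
    path = tmp_path / "out.pdb"
    cn.write_structure(s, path)
    back = cn.read_structure(path, chain="A")
    assert back.one_letter_sequence() == "ACDEFG"
    for a, b in zip(s.residues, back.residues):
        assert np.allclose(a.coords, b.coords, atol=1e-3)
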