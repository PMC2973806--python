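import numpy as np
import pytest

import catnets as cn
from catnets.alignment import AA_INDEX
from catnets.conservation import load_background


def simple_spec(**kwargs):
    defaults = dict(
        n_sequences=200,
        n_columns=20,
        catalytic_columns=(4, 11),
        conservation_level=0.15,
        coevolving_pairs=((4, 8, 0.8), (11, 15, 0.8)),
        n_duplicate_clusters=2,
        contact_radius=8.0,
        seed=7,
    )
    defaults.update(kwargs)
    return cn.FamilySpec(**defaults)


class TestGenerateFamily:
    def test_shapes_and_annotation(self):
        fam = cn.generate_family(simple_spec())
        assert fam.alignment.n_sequences == 200
        assert fam.alignment.n_columns == 20
        assert len(fam.structure) == 20
        assert fam.catalytic_residues == {("A", 5, " "), ("A", 12, " ")}

    def test_deterministic_outputs(self, tmp_path):
        spec = simple_spec()
        a, b = cn.generate_family(spec), cn.generate_family(spec)
        assert a.alignment.rows == b.alignment.rows
        pa = cn.write_family(a, tmp_path / "a")
        pb = cn.write_family(b, tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()

    def test_fully_conserved_column_hits_background_kl(self):
        lv = np.full(20, 0.15)
        lv[2] = 1.0
        fam = cn.generate_family(simple_spec(conservation_level=lv, gap_fraction=0.0))
        prof = cn.column_frequencies(cn.trim_alignment(fam.alignment))
        kl = cn.kl_conservation(prof)
        consensus = fam.alignment.rows[0][2]
        q = load_background()[AA_INDEX[consensus]]
        assert kl[2] == pytest.approx(np.log2(1.0 / q))

    def test_empirical_frequencies_converge_to_spec(self):
        lv = np.full(8, 0.6)
        spec = cn.FamilySpec(
            n_sequences=5000, n_columns=8, catalytic_columns=(0,),
            conservation_level=lv, coevolving_pairs=(), n_duplicate_clusters=0,
            contact_radius=8.0, seed=1, gap_fraction=0.0,
        )
        fam = cn.generate_family(spec)
        prof = cn.column_frequencies(fam.alignment)
        consensus_freq = prof.frequencies.max(axis=1)
        background_top = load_background().max()
        expected = 0.6 + 0.4 * 0  # consensus draws, ignoring background hits
        assert np.all(np.abs(consensus_freq - expected) < 0.02 + 0.4 * background_top)

    def test_planted_full_coupling_is_mi_maximum(self):
        # a 50/50 two-state pair carries a full bit of MI, above the
        # small-sample bias of any 20-state background pair at n = 500
        lv = np.full(20, 0.15)
        lv[4] = 0.5
        spec = simple_spec(
            n_sequences=500, coevolving_pairs=((4, 8, 1.0),), conservation_level=lv,
            n_duplicate_clusters=0, gap_fraction=0.0, seed=11,
        )
        fam = cn.generate_family(spec)
        mi = cn.pair_mi(fam.alignment, pseudocount=False)
        iu = np.triu_indices(20, k=1)
        best = np.nanargmax(mi[iu])
        assert (iu[0][best], iu[1][best]) == (4, 8)

    def test_no_coupling_yields_no_significant_z(self):
        spec = simple_spec(
            n_sequences=300, coevolving_pairs=(), n_duplicate_clusters=0, seed=5
        )
        fam = cn.generate_family(spec)
        result = cn.permutation_zscores(
            cn.trim_alignment(fam.alignment), n_permutations=50, seed=3
        )
        iu = np.triu_indices(fam.alignment.n_columns, k=1)
        z = result.zscores[iu]
        assert np.nanmax(z) < 6.0

    def test_pdb_roundtrip(self, tmp_path):
        fam = cn.generate_family(simple_spec())
        paths = cn.write_family(fam, tmp_path)
        back = cn.read_structure(paths["structure"], chain="A")
        assert len(back) == len(fam.structure)
        for a, b in zip(fam.structure.residues, back.residues):
            assert np.allclose(a.coords, b.coords, atol=1e-3)

    def test_site_geometry(self):
        spec = simple_spec()
        fam = cn.generate_family(spec)
        coords = np.array([r.coords[0] for r in fam.structure.residues])
        cat_idx, partner_idx = [4, 11], [8, 15]
        filler_idx = [0, 1, 2, 3]  # first non-site columns pad the site
        chain_idx = [
            i for i in range(20) if i not in cat_idx + partner_idx + filler_idx
        ]
        # catalytic residues on a shell near the site center, mutually spread
        for c in cat_idx:
            assert 4.2 <= np.linalg.norm(coords[c]) <= 5.0
        assert np.linalg.norm(coords[4] - coords[11]) >= 6.0
        # each partner sits in the outer shell around its coupled residue
        for p, c in [(8, 4), (15, 11)]:
            dist = np.linalg.norm(coords[p] - coords[c])
            assert 0.68 * spec.contact_radius - 1e-6 <= dist <= 0.95 * spec.contact_radius + 1e-6
        # filler inside the site sphere, chain residues outside it
        for f in filler_idx:
            assert 3.0 <= np.linalg.norm(coords[f]) <= 0.7 * spec.contact_radius
        for o in chain_idx:
            gap = min(np.linalg.norm(coords[o] - coords[c]) for c in cat_idx)
            assert gap >= spec.contact_radius + 0.75  # outside every contact sphere
            assert np.linalg.norm(coords[o]) <= spec.contact_radius + 6.0  # compact

    def test_infeasible_geometry_raises(self):
        spec = simple_spec(
            n_columns=40,
            catalytic_columns=(0, 1),
            coevolving_pairs=tuple((0, j, 0.8) for j in range(2, 30)),
            contact_radius=4.5,
        )
        with pytest.raises(ValueError, match="contact_radius"):
            cn.generate_family(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            simple_spec(catalytic_columns=(99,))
        with pytest.raises(ValueError):
            simple_spec(coevolving_pairs=((1, 2, 1.5),))
        with pytest.raises(ValueError):
            simple_spec(conservation_level=0.0)


class TestGenerateBenchmark:
    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="at least 5"):
            cn.generate_benchmark(4, "easy", seed=0)

    def test_easy_benchmark_spans_small_and_large_families(self):
        fams = cn.generate_benchmark(8, "easy", seed=2)
        sizes = [f.alignment.n_sequences for f in fams]
        assert min(sizes) < 10 and max(sizes) >= 400

    def test_hard_benchmark_is_deep(self):
        fams = cn.generate_benchmark(5, "hard", seed=2)
        assert all(300 <= f.alignment.n_sequences <= 600 for f in fams)
        assert all(len(f.catalytic_residues) == 3 for f in fams)

    def test_determinism(self):
        a = cn.generate_benchmark(5, "hard", seed=9)
        b = cn.generate_benchmark(5, "hard", seed=9)
        assert all(x.alignment.rows == y.alignment.rows for x, y in zip(a, b))
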