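import numpy as np
import pytest

import catnets as cn

FASTA3 = """>ref
AC-DE
>s1
ACGDE
>s2
AC-D-
"""

STOCKHOLM = """# STOCKHOLM 1.0
ref   AC.DE
s1    ACGDE
//
"""


class TestReadAlignment:
    def test_fasta_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(FASTA3)
        aln = cn.read_alignment(p, "fasta", "ref")
        assert aln.n_sequences == 3 and aln.n_columns == 5
        assert aln.reference_row == "AC-DE"

    def test_missing_reference(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(FASTA3)
        with pytest.raises(ValueError, match="reference not found"):
            cn.read_alignment(p, "fasta", "nope")

    def test_stockholm_dot_gaps_normalized(self, tmp_path):
        p = tmp_path / "a.sto"
        p.write_text(STOCKHOLM)
        aln = cn.read_alignment(p, "stockholm", "ref")
        assert aln.rows[0] == "AC-DE"
        assert "." not in "".join(aln.rows)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            cn.read_alignment(p, "fasta", "ref")

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ref\nacde\n>s1\nacde\n")
        aln = cn.read_alignment(p, "fasta", "ref")
        assert aln.rows[0] == "ACDE"

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="row 1"):
            cn.Alignment(["a", "b"], ["ACD", "AC"], "a")


class TestTrim:
    def test_reference_gap_columns_removed(self):
        aln = cn.Alignment(["r", "s"], ["A-C", "AGC"], "r")
        out = cn.trim_alignment(aln)
        assert out.reference_row == "AC" and out.n_columns == 2

    def test_majority_gap_column_removed(self):
        # 3 gaps of 4 (75% > 50%) in the second column
        rows = ["AA", "A-", "A-", "A-"]
        aln = cn.Alignment(list("rstu"), rows, "r")
        out = cn.trim_alignment(aln)
        assert out.n_columns == 1

    def test_half_gap_column_kept(self):
        rows = ["AA", "A-", "A-", "AC"]  # exactly 50% gaps: kept
        aln = cn.Alignment(list("rstu"), rows, "r")
        assert cn.trim_alignment(aln).n_columns == 2

    def test_low_coverage_sequence_removed(self):
        ref = "ACDEFGHIKL"  # trimmed length 10
        low = "ACDE------"  # 4 residues -> 40% coverage
        ok = "ACDEF-----"  # 5 residues -> exactly 50%: kept
        full = ["ACDEFGHIKL"] * 4  # keep every column under 50% gaps
        aln = cn.Alignment(
            ["r", "x", "y", "f1", "f2", "f3", "f4"], [ref, low, ok] + full, "r"
        )
        out = cn.trim_alignment(aln)
        assert out.sequence_ids == ["r", "y", "f1", "f2", "f3", "f4"]

    def test_idempotent(self, random_alignment):
        aln = random_alignment(12, 30, seed=3, gap_fraction=0.3)
        once = cn.trim_alignment(aln)
        twice = cn.trim_alignment(once)
        assert once.rows == twice.rows and once.sequence_ids == twice.sequence_ids

    def test_all_columns_removed(self):
        aln = cn.Alignment(["r", "s"], ["---", "ACD"], "r")
        with pytest.raises(ValueError, match="empty alignment"):
            cn.trim_alignment(aln)


class TestClusterWeights:
    def test_duplicates_share_cluster(self):
        aln = cn.Alignment(["a", "b", "c"], ["AAAA", "AAAA", "CDEF"], "a")
        w = cn.cluster_weights(aln)
        assert np.allclose(w.weights, [0.5, 0.5, 1.0])
        assert w.n_clusters == 2

    def test_all_distinct_singletons(self, random_alignment):
        aln = random_alignment(6, 40, seed=1)
        w = cn.cluster_weights(aln)
        assert np.allclose(w.weights, 1.0)

    def test_four_copies(self):
        aln = cn.Alignment(list("abcd"), ["ACDE"] * 4, "a")
        assert np.allclose(cn.cluster_weights(aln).weights, 0.25)

    def test_weights_sum_to_cluster_count(self, random_alignment):
        aln = random_alignment(25, 12, seed=5)
        w = cn.cluster_weights(aln)
        assert np.isclose(w.weights.sum(), w.n_clusters)

    def test_row_permutation_equivariance(self, random_alignment):
        aln = random_alignment(15, 10, seed=7)
        w = cn.cluster_weights(aln).weights
        perm = np.random.default_rng(0).permutation(15)
        shuffled = cn.Alignment(
            [aln.sequence_ids[i] for i in perm], [aln.rows[i] for i in perm],
            aln.sequence_ids[perm[0]],
        )
        assert np.allclose(cn.cluster_weights(shuffled).weights, w[perm])

    def test_identity_ignores_gap_columns(self):
        # identity over columns where both have residues: 2/2 matches
        aln = cn.Alignment(["a", "b"], ["AC--", "AC-D"], "a")
        assert cn.cluster_weights(aln).n_clusters == 1


class TestStructureMapping:
    def test_identity_mapping(self):
        from .conftest_helpers import structure_from_sequence

        s = structure_from_sequence("ACDE")
        aln = cn.Alignment(["r", "s"], ["ACDE", "ACDF"], "r")
        mapped = cn.map_columns_to_structure(aln, s)
        assert mapped.column_map == [("A", i + 1, " ") for i in range(4)]

    def test_nterminal_offset(self):
        from .conftest_helpers import structure_from_sequence

        s = structure_from_sequence("GGACDE")
        aln = cn.Alignment(["r", "s"], ["ACDE", "ACDE"], "r")
        mapped = cn.map_columns_to_structure(aln, s)
        assert mapped.column_map[0] == ("A", 3, " ")

    def test_unrelated_sequence_fails(self):
        from .conftest_helpers import structure_from_sequence

        s = structure_from_sequence("WWWWYYYYFFFF")
        aln = cn.Alignment(["r", "s"], ["KKKKRRRRHHHH", "KKKKRRRRHHHH"], "r")
        with pytest.raises(ValueError, match="mismatch"):
            cn.map_columns_to_structure(aln, s)

    def test_gapped_reference_rejected(self):
        from .conftest_helpers import structure_from_sequence

        s = structure_from_sequence("ACDE")
        aln = cn.Alignment(["r", "s"], ["AC-E", "ACDE"], "r")
        with pytest.raises(ValueError, match="trim"):
            cn.map_columns_to_structure(aln, s)
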