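import numpy as np
import pytest
from hypothesis import settings

import catnets as cn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


TOY_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  H   ALA A   1       9.000   9.000   9.000  1.00  0.00           H
ATOM      4  CA  CYS A   2       4.000   4.000   0.000  1.00  0.00           C
ATOM      5  CB  CYS A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      6  CA  ASP A   3       8.000   0.000   0.000  1.00  0.00           C
ATOM      7  O   HOH A   4       2.000   2.000   2.000  1.00  0.00           O
ATOM      8  CA  GLY B   1       0.000   0.000   5.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1      50.000  50.000  50.000  1.00  0.00           C
ATOM      2  CA  CYS A   2      54.000  54.000  50.000  1.00  0.00           C
ATOM      3  CA  ASP A   3      58.000  50.000  50.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def make_structure(coords, names=None, chain="A"):
    """Build a toy structure with one pseudo-atom per residue."""
    coords = np.asarray(coords, dtype=float)
    names = names or ["ALA"] * len(coords)
    residues = [
        cn.Residue(chain=chain, number=i + 1, icode=" ", name=names[i], coords=coords[i][None, :])
        for i in range(len(coords))
    ]
    return cn.Structure(residues=residues)


@pytest.fixture
def random_alignment():
    def _make(n_seq, n_col, seed=0, gap_fraction=0.0):
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        chars = letters[rng.integers(0, 20, size=(n_seq, n_col))]
        if gap_fraction:
            mask = rng.random(chars.shape) < gap_fraction
            mask[0] = False
            chars[mask] = "-"
        rows = ["".join(r) for r in chars]
        ids = [f"s{i}" for i in range(n_seq)]
        return cn.Alignment(ids, rows, ids[0])

    return _make


@pytest.fixture(scope="session")
def hard_benchmark():
    """The planted hard benchmark: 20 families with partially conserved
    catalytic columns, coupling-0.8 coevolving partners inside the 8 A
    site sphere, and conserved decoy columns."""
    families = cn.generate_benchmark(20, "hard", seed=0)
    return [
        cn.prepare_family(fam, n_permutations=100, seed=1000 + i)
        for i, fam in enumerate(families)
    ]
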