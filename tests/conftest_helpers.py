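"""Shared helpers for building toy structures in tests."""

import numpy as np
from Bio.SeqUtils import seq3

import catnets as cn


def structure_from_sequence(seq, spacing=3.8, chain="A"):
    """A straight-chain toy structure with one atom per residue."""
    residues = [
        cn.Residue(
            chain=chain,
            number=i + 1,
            icode=" ",
            name=seq3(ch).upper(),
            coords=np.array([[i * spacing, 0.0, 0.0]]),
        )
        for i, ch in enumerate(seq)
    ]
    return cn.Structure(residues=residues)
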