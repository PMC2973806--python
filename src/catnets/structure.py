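"""Protein structures, inter-residue distances, and proximity network scores.

Distances between residues are minimum heavy-atom (non-hydrogen) distances
in Angstrom. The per-residue network scores defined here are:

cMI
    cumulative mutual information — the sum of a column's APC-corrected MI
    over all partners whose MI Z-score passes a threshold;
pMI / pC
    proximity averages — for each residue, the mean cMI (resp. KL
    conservation) of its spatial neighbors within a distance threshold,
    min-max rescaled to [0, 1] per family.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from Bio.PDB import PDBIO, PDBParser, StructureBuilder
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1, seq3

from .alignment import ResidueKey
from .mi import MIResult

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Residue:
    """One amino-acid residue with its heavy-atom coordinates (Angstrom)."""

    chain: str
    number: int
    icode: str
    name: str
    coords: np.ndarray  # (n_heavy_atoms, 3)

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.number, self.icode)


@dataclasses.dataclass
class Structure:
    """An ordered single-chain list of residues from one model."""

    residues: list[Residue]
    model_index: int = 1

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in structure")
        for r in self.residues:
            if len(r.coords) < 1:
                raise ValueError(f"residue {r.key} has no heavy atoms")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def one_letter_sequence(self) -> str:
        return "".join(seq1(r.name, undef_code="X") for r in self.residues)


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric residue-by-residue minimum heavy-atom distances."""

    distances: np.ndarray
    residue_keys: list[ResidueKey]


def read_structure(path: str | Path, chain: str = "A", model: int = 1) -> Structure:
    """Read one chain of one model from a PDB file.

    Only standard amino-acid residues are kept (waters and other hetero
    groups are dropped), hydrogens are excluded, and alternate locations
    resolve to the highest-occupancy conformer. ``model`` is 1-based file
    order; multi-model (NMR) files default to the first model.
    """
    parser = PDBParser(QUIET=True)
    pdb = parser.get_structure("s", str(path))
    models = list(pdb)
    if not models:
        raise ValueError(f"no models in {path}")
    if model < 1 or model > len(models):
        raise ValueError(f"model {model} not in file ({len(models)} models)")
    mdl = models[model - 1]
    chains = [c.id for c in mdl]
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    residues = []
    for res in mdl[chain]:
        het, num, icode = res.id
        if het != " " or not is_aa(res, standard=True):
            continue
        coords = [
            atom.get_coord()
            for atom in res.get_atoms()  # picks highest-occupancy altloc
            if (atom.element or "").upper() not in ("H", "D")
        ]
        if not coords:
            continue
        residues.append(
            Residue(
                chain=chain,
                number=int(num),
                icode=icode.strip() or " ",
                name=res.get_resname(),
                coords=np.asarray(coords, dtype=float),
            )
        )
    if not residues:
        raise ValueError(f"chain {chain!r} contains no standard amino-acid residues")
    return Structure(residues=residues, model_index=model)


def write_structure(
    structure: Structure, path: str | Path, bfactors: Optional[dict] = None
) -> None:
    """Write the structure as a single-model PDB file (CA-style atoms).

    Residues with one pseudo-atom are written as CA records; residues with
    full atom lists are written with generic atom names. ``bfactors`` maps
    residue keys to a per-residue score stored in the B-factor column, for
    coloring any of the computed scores in a molecular viewer.
    """
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_seg("    ")
    chains_done = set()
    for res in structure.residues:
        if res.chain not in chains_done:
            builder.init_chain(res.chain)
            chains_done.add(res.chain)
        builder.init_residue(res.name, " ", res.number, res.icode)
        score = float(bfactors.get(res.key, 0.0)) if bfactors else 0.0
        for a, xyz in enumerate(res.coords):
            name = "CA" if len(res.coords) == 1 else f"X{a + 1}"
            builder.init_atom(name, np.asarray(xyz, float), score, 1.0, " ", name, element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


def residue_distance_matrix(structure: Structure) -> DistanceMatrix:
    """Minimum heavy-atom distance between every residue pair."""
    n = len(structure)
    if n < 2:
        raise ValueError("need at least 2 residues for a distance matrix")
    coords = np.concatenate([r.coords for r in structure.residues])
    owner = np.concatenate(
        [np.full(len(r.coords), i) for i, r in enumerate(structure.residues)]
    )
    atom_d = cdist(coords, coords)
    dm = np.full((n, n), np.inf)
    np.minimum.at(dm, (owner[:, None], owner[None, :]), atom_d)
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(distances=dm, residue_keys=structure.residue_keys())


def cumulative_mi(mi: MIResult, z_threshold: float) -> np.ndarray:
    """Per-column cumulative MI.

    cMI_i = sum of APC-corrected MI over all partners j with Z_ij >=
    z_threshold (0 when no pair passes). Any negative APC value passing the
    threshold is included as-is.
    """
    passing = mi.zscores >= z_threshold  # NaN compares False: diagonal excluded
    return np.where(passing, mi.mi_apc, 0.0).sum(axis=1)


def proximity_average(
    values: np.ndarray,
    dm: DistanceMatrix,
    distance_threshold: float,
    include_self: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Neighborhood average of a per-residue score, min-max rescaled to [0,1].

    For each residue the mean of ``values`` over neighbors at distance
    0 < d <= ``distance_threshold`` (the residue itself excluded unless
    ``include_self``); residues with no neighbors score 0. The average is
    divided by the neighbor count, so the score carries no implicit
    solvent-exposure bias. Finally min-max rescaled across the family; a
    constant vector degenerates to all zeros.
    """
    if distance_threshold <= 0:
        raise ValueError("distance_threshold must be positive")
    values = np.asarray(values, dtype=float)
    d = dm.distances
    if values.shape[0] != d.shape[0]:
        raise ValueError("values do not match the distance matrix")
    neighbor = (d > 0) & (d <= distance_threshold)
    if include_self:
        neighbor = neighbor | np.eye(len(values), dtype=bool)
    counts = neighbor.sum(axis=1)
    if np.all(counts == 0):
        logger.warning("all residues isolated at %.2f A; proximity average is 0", distance_threshold)
        return np.zeros_like(values)
    avg = np.where(counts > 0, neighbor @ values / np.maximum(counts, 1), 0.0)
    if not normalize:
        return avg
    lo, hi = avg.min(), avg.max()
    if hi <= lo:
        return np.zeros_like(avg)
    return (avg - lo) / (hi - lo)
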