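"""Synthetic protein families with planted signals.

Each generated family emulates the inputs of the catalytic-residue
benchmark: a multiple sequence alignment with planted conserved columns,
planted coevolving column pairs and phylogenetic redundancy (near-duplicate
sequences), a toy 3-D structure in which the catalytic residues and their
coevolving partners form a spatial cluster, and a catalytic annotation.

The sequence model per column is: draw the column's consensus residue with
probability ``conservation_level``, otherwise draw from the amino-acid
background. A coevolving pair (i, j, s) replaces the two columns by a
two-state code (consensus/alternative residue per column); with probability
``s`` the partner column copies the state of column i, otherwise it draws
its state independently — so coupling 1.0 on a 50/50 column yields exactly
1 bit of mutual information and coupling 0 yields none.

The structure places one pseudo-atom (a C-alpha-like center) per residue:
catalytic residues sit in a tight cluster at the origin, their coevolving
partners inside a sphere of radius ``contact_radius`` around that cluster,
and all remaining residues on a self-avoiding random walk (3.8 A steps)
kept outside the site sphere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.SeqUtils import seq3

from .alignment import AA_ALPHABET, Alignment, ResidueKey
from .cls import FamilyRecord
from .conservation import N_AA, load_background
from .structure import Residue, Structure, write_structure

CHAIN_ID = "A"
STEP = 3.8  # Cα-Cα virtual bond length, A
MIN_SEP = 3.4  # clash distance between placed centers, A
DUPLICATE_COPIES = 3
DUPLICATE_NOISE = 0.02  # per-residue mutation rate within a duplicate cluster


@dataclasses.dataclass
class FamilySpec:
    """Controls for one synthetic family."""

    n_sequences: int = 400
    n_columns: int = 50
    catalytic_columns: tuple[int, ...] = (10, 24, 38)
    conservation_level: float | Sequence[float] = 0.15
    coevolving_pairs: tuple[tuple[int, int, float], ...] = ()
    n_duplicate_clusters: int = 3
    contact_radius: float = 8.0
    seed: int = 0
    gap_fraction: float = 0.02
    #: columns lining the inside of the site sphere (no coupling; typically
    #: moderately conserved, like real second-shell residues). None = pick
    #: the first non-site columns automatically.
    filler_columns: Optional[tuple[int, ...]] = None

    def levels(self) -> np.ndarray:
        lv = np.broadcast_to(
            np.asarray(self.conservation_level, dtype=float), (self.n_columns,)
        ).copy()
        if np.any((lv <= 0) | (lv > 1)):
            raise ValueError("conservation_level entries must lie in (0, 1]")
        return lv

    def __post_init__(self) -> None:
        if not all(0 <= c < self.n_columns for c in self.catalytic_columns):
            raise ValueError("catalytic_columns out of range")
        if not self.catalytic_columns:
            raise ValueError("need at least one catalytic column")
        for i, j, s in self.coevolving_pairs:
            if not (0 <= i < self.n_columns and 0 <= j < self.n_columns) or i == j:
                raise ValueError(f"bad coevolving pair ({i}, {j})")
            if not 0.0 <= s <= 1.0:
                raise ValueError("coupling strengths must lie in [0, 1]")
        if self.contact_radius <= STEP:
            raise ValueError("contact_radius must exceed one chain step")
        self.levels()


def _draw_background(rng: np.random.Generator, size, background: np.ndarray) -> np.ndarray:
    return rng.choice(N_AA, size=size, p=background)


def _sample_msa(spec: FamilySpec, rng: np.random.Generator, background: np.ndarray):
    """Integer-coded MSA (n_sequences x n_columns) plus consensus codes."""
    levels = spec.levels()
    n_dup = spec.n_duplicate_clusters
    n_base = spec.n_sequences - DUPLICATE_COPIES * n_dup
    if n_base < max(1, n_dup):
        raise ValueError("n_sequences too small for the requested duplicate clusters")

    consensus = _draw_background(rng, spec.n_columns, background)
    alt = _draw_background(rng, spec.n_columns, background)
    clash = alt == consensus
    while np.any(clash):
        alt[clash] = _draw_background(rng, int(clash.sum()), background)
        clash = alt == consensus

    is_consensus = rng.random((n_base, spec.n_columns)) < levels[None, :]
    noise = _draw_background(rng, (n_base, spec.n_columns), background)
    msa = np.where(is_consensus, consensus[None, :], noise)

    # two-state coevolving columns; a column may drive several partners but
    # can itself be a partner only once
    state: dict[int, np.ndarray] = {}
    for i, j, s in spec.coevolving_pairs:
        if j in state:
            raise ValueError(f"column {j} is the partner of more than one pair")
        if i not in state:
            state[i] = rng.random(n_base) >= levels[i]  # True = alternative state
        coupled = rng.random(n_base) < s
        independent = rng.random(n_base) >= levels[i]
        state[j] = np.where(coupled, state[i], independent)
    for col, st in state.items():
        msa[:, col] = np.where(st, alt[col], consensus[col])

    if n_dup:
        sources = rng.choice(n_base, size=n_dup, replace=False)
        copies = []
        for src in sources:
            for _ in range(DUPLICATE_COPIES):
                mutated = msa[src].copy()
                flip = rng.random(spec.n_columns) < DUPLICATE_NOISE
                mutated[flip] = _draw_background(rng, int(flip.sum()), background)
                copies.append(mutated)
        msa = np.vstack([msa, np.array(copies)])
    return msa, consensus


def _place_site(
    n_points: int,
    lo: float,
    hi: float,
    existing: list[np.ndarray],
    rng: np.random.Generator,
    min_sep: float,
    max_tries: int = 5000,
) -> list[np.ndarray]:
    """Place points uniformly in the shell lo <= |x| <= hi, min_sep apart."""
    placed: list[np.ndarray] = []
    for _ in range(n_points):
        for attempt in range(max_tries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = (lo**3 + (hi**3 - lo**3) * rng.random()) ** (1.0 / 3.0)
            candidate = radius * direction
            others = existing + placed
            if all(np.linalg.norm(candidate - p) >= min_sep for p in others):
                placed.append(candidate)
                break
        else:
            raise ValueError(
                "infeasible site geometry: could not place "
                f"{n_points} residues within {hi:.1f} A; increase contact_radius"
            )
    return placed


def _place_anchored(
    anchor: np.ndarray,
    lo: float,
    hi: float,
    max_norm: float,
    existing: list[np.ndarray],
    rng: np.random.Generator,
    max_tries: int = 5000,
) -> np.ndarray:
    """One point at distance U[lo, hi] from ``anchor``, clash-free and
    within ``max_norm`` of the site center."""
    for _ in range(max_tries):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        candidate = anchor + rng.uniform(lo, hi) * direction
        if np.linalg.norm(candidate) > max_norm:
            continue
        if all(np.linalg.norm(candidate - p) >= MIN_SEP for p in existing):
            return candidate
    raise ValueError(
        "infeasible site geometry: could not place a coevolving partner; "
        "increase contact_radius"
    )


def _generate_coordinates(
    spec: FamilySpec,
    partner_anchor: dict[int, int],
    filler: Sequence[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Coordinates embodying the planted active-site geometry.

    Seen from a catalytic residue, the site is layered: a tight catalytic
    cluster near the center, ordinary (low-cMI) filler residues within
    ~0.7 x contact_radius, the coevolving partners in a shell at
    0.72-0.98 x contact_radius, and the rest of the chain random-walking
    outside contact_radius + 2 A. The proximity-MI signal around a
    catalytic residue therefore saturates at the contact radius: smaller
    neighborhoods see mostly filler, larger ones dilute into the chain.
    """
    n = spec.n_columns
    radius = spec.contact_radius
    coords = np.full((n, 3), np.nan)
    catalytic = list(spec.catalytic_columns)

    cat_hi = max(5.0, 1.2 * len(catalytic))
    for col, xyz in zip(
        catalytic, _place_site(len(catalytic), 4.2, cat_hi, [], rng, min_sep=6.0)
    ):
        coords[col] = xyz
    placed = [coords[c] for c in catalytic]

    for col, anchor_col in partner_anchor.items():
        anchor = coords[anchor_col]
        if np.isnan(anchor[0]):
            anchor = coords[catalytic[int(rng.integers(len(catalytic)))]]
        coords[col] = _place_anchored(
            anchor, 0.68 * radius, 0.95 * radius, radius + 0.5, placed, rng
        )
        placed.append(coords[col])

    for col, xyz in zip(
        filler, _place_site(len(filler), 3.0, 0.7 * radius, placed, rng, MIN_SEP)
    ):
        coords[col] = xyz
        placed.append(coords[col])

    # remaining residues: self-avoiding walk orbiting the site in a compact
    # shell, as in a globular protein — outside every catalytic residue's
    # contact sphere but never escaping to infinity, so neighborhoods larger
    # than the contact radius dilute into ordinary chain
    cat_coords = [coords[c] for c in catalytic]
    shell_lo = radius + 0.75  # from the nearest catalytic residue
    shell_hi = radius + 6.0  # from the site center
    remaining = [c for c in range(n) if np.isnan(coords[c, 0])]
    current = None
    for col in remaining:
        for attempt in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if current is None:
                candidate = (radius + 2.5) * direction
            else:
                candidate = current + STEP * direction
            outside_site = all(
                np.linalg.norm(candidate - c) >= shell_lo for c in cat_coords
            )
            compact = np.linalg.norm(candidate) <= shell_hi
            clear = all(np.linalg.norm(candidate - p) >= MIN_SEP for p in placed)
            if outside_site and compact and clear:
                coords[col] = candidate
                placed.append(candidate)
                current = candidate
                break
            if attempt % 100 == 99:
                current = None  # restart the walk from a fresh entry point
        else:
            raise ValueError("could not grow the chain; increase contact_radius")
    return coords


def generate_family(spec: FamilySpec, identifier: Optional[str] = None) -> FamilyRecord:
    """Generate one synthetic family. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    background = load_background()
    msa, _consensus = _sample_msa(spec, rng, background)

    letters = np.array(list(AA_ALPHABET))
    rows = ["".join(r) for r in letters[msa]]
    # reference row stays gap-free; sprinkle gaps over the other rows
    if spec.gap_fraction > 0:
        chars = np.array([list(r) for r in rows])
        gap_mask = rng.random(chars.shape) < spec.gap_fraction
        gap_mask[0] = False
        chars[gap_mask] = "-"
        rows = ["".join(r) for r in chars]
    ids = [f"seq{i:04d}" for i in range(len(rows))]
    aln = Alignment(sequence_ids=ids, rows=rows, reference_id=ids[0])

    # anchor each non-catalytic member of a coevolving pair to its coupled
    # column (placed members first, catalytic preferred)
    partner_anchor: dict[int, int] = {}
    for i, j, _s in spec.coevolving_pairs:
        for member, other in ((i, j), (j, i)):
            if member not in spec.catalytic_columns and member not in partner_anchor:
                partner_anchor[member] = other
    site = set(spec.catalytic_columns) | set(partner_anchor)
    if spec.filler_columns is not None:
        overlap = site & set(spec.filler_columns)
        if overlap:
            raise ValueError(f"filler_columns overlap the site: {sorted(overlap)}")
        filler = list(spec.filler_columns)
    else:
        n_filler = min(2 * len(spec.catalytic_columns), spec.n_columns - len(site))
        filler = [c for c in range(spec.n_columns) if c not in site][:n_filler]
    coords = _generate_coordinates(spec, partner_anchor, filler, rng)

    ref = rows[0]
    residues = [
        Residue(
            chain=CHAIN_ID,
            number=col + 1,
            icode=" ",
            name=seq3(ref[col]).upper(),
            coords=coords[col][None, :],
        )
        for col in range(spec.n_columns)
    ]
    structure = Structure(residues=residues, model_index=1)
    catalytic_keys: set[ResidueKey] = {
        (CHAIN_ID, col + 1, " ") for col in spec.catalytic_columns
    }
    return FamilyRecord(
        alignment=aln,
        structure=structure,
        catalytic_residues=catalytic_keys,
        identifier=identifier or f"synth-{spec.seed}",
    )


def _benchmark_spec(
    difficulty: str, seed: int, n_sequences: int, rng: np.random.Generator
) -> FamilySpec:
    n_columns = int(rng.integers(40, 56))
    positions = rng.permutation(n_columns)
    catalytic = tuple(sorted(int(p) for p in positions[:3]))
    partners_per_site = 3 if difficulty == "hard" else 0
    n_partners = 3 * partners_per_site
    partner_cols = [int(p) for p in positions[3 : 3 + n_partners]]
    n_decoys = 6 if difficulty == "hard" else 5
    decoy_cols = [int(p) for p in positions[3 + n_partners : 3 + n_partners + n_decoys]]
    used = 3 + n_partners + n_decoys
    filler_cols = tuple(int(p) for p in positions[used : used + 6])

    levels = np.full(n_columns, 0.15)
    # the residues lining an active site are themselves fairly conserved —
    # this is what gives the proximity-conservation (pC) term its signal
    levels[list(filler_cols)] = rng.uniform(0.45, 0.7, size=len(filler_cols))
    if difficulty == "hard":
        # catalytic conservation too weak to beat the decoys; the signal
        # that rescues them is the planted coevolution network
        levels[list(catalytic)] = rng.uniform(0.5, 0.7, size=3)
        levels[decoy_cols] = rng.uniform(0.85, 0.95, size=n_decoys)
        coupling = 0.8
    else:
        # fully conserved catalytic columns dominate the milder decoys, so
        # conservation alone suffices; a fully conserved column cannot
        # covary, hence no coevolving pairs in this regime
        levels[list(catalytic)] = 1.0
        levels[decoy_cols] = 0.6
        coupling = 0.0
    pairs = tuple(
        (catalytic[k // partners_per_site], partner_cols[k], coupling)
        for k in range(n_partners)
    )
    n_dup = 3 if n_sequences >= 30 else 0
    return FamilySpec(
        n_sequences=n_sequences,
        n_columns=n_columns,
        catalytic_columns=catalytic,
        conservation_level=levels,
        coevolving_pairs=pairs,
        n_duplicate_clusters=n_dup,
        filler_columns=filler_cols,
        contact_radius=8.0,
        seed=seed,
    )


def generate_benchmark(
    n_families: int, difficulty: str = "hard", seed: int = 0
) -> list[FamilyRecord]:
    """A benchmark of synthetic families.

    ``easy`` families have fully conserved catalytic columns and MSA sizes
    log-spread over 5-600 sequences (so conservation alone suffices when
    enough sequences are present); ``hard`` families have catalytic columns
    at conservation 0.5-0.7, coupling-0.8 coevolving partners inside the
    8 A contact sphere, and highly conserved non-catalytic decoy columns —
    the regime where conservation alone fails — with 300-600 sequences, the
    depth needed for reliable MI estimates.
    """
    if n_families < 5:
        raise ValueError("a benchmark needs at least 5 families")
    if difficulty not in ("easy", "hard"):
        raise ValueError("difficulty must be 'easy' or 'hard'")
    rng = np.random.default_rng(seed)
    if difficulty == "easy":
        sizes = np.unique(
            np.round(np.logspace(np.log10(5), np.log10(600), n_families)).astype(int)
        )
        sizes = rng.permutation(
            np.resize(sizes, n_families)
        )
    else:
        sizes = np.exp(
            rng.uniform(np.log(300), np.log(600), size=n_families)
        ).astype(int)
    families = []
    for k in range(n_families):
        spec = _benchmark_spec(
            difficulty, seed=int(rng.integers(0, 2**31 - 1)), n_sequences=int(sizes[k]), rng=rng
        )
        families.append(generate_family(spec, identifier=f"{difficulty}-{k:02d}"))
    return families


def write_family(record: FamilyRecord, directory: str | Path) -> dict[str, Path]:
    """Write a family as alignment.fasta + structure.pdb + catalytic.tsv."""
    from .alignment import write_alignment

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": directory / "alignment.fasta",
        "structure": directory / "structure.pdb",
        "annotation": directory / "catalytic.tsv",
    }
    write_alignment(record.alignment, paths["alignment"])
    write_structure(record.structure, paths["structure"])
    with open(paths["annotation"], "w") as fh:
        fh.write("# chain\tresidue_number\tcatalytic\n")
        for chain, number, _icode in sorted(record.catalytic_residues):
            fh.write(f"{chain}\t{number}\t1\n")
    return paths
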