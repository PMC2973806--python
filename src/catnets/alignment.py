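"""Multiple sequence alignment handling.

Reading and validation, gap trimming relative to a reference sequence,
redundancy weighting by identity clustering, and mapping of alignment
columns onto structure residues.

Alignment columns are 0-based internally; every user-facing report uses the
structure's author residue numbering instead.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
GAP = "-"
#: integer code shared by gaps and non-standard symbols ('X', 'B', ...);
#: both are excluded from frequency counting.
GAP_CODE = 20

#: (chain id, author residue number, insertion code)
ResidueKey = tuple[str, int, str]


@dataclasses.dataclass
class Alignment:
    """A rectangular multiple sequence alignment with a designated reference.

    Parameters
    ----------
    sequence_ids
        Unique identifier per row.
    rows
        Equal-length uppercase strings over the 20 amino acids, ``-`` and
        ``X``.
    reference_id
        Identifier of the reference row; must occur in ``sequence_ids``.
    column_map
        Optional per-column structure residue key (or ``None`` for columns
        without a mapped residue), filled by
        :func:`map_columns_to_structure`.
    """

    sequence_ids: list[str]
    rows: list[str]
    reference_id: str
    column_map: Optional[list[Optional[ResidueKey]]] = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no sequences")
        width = len(self.rows[0])
        if width < 1:
            raise ValueError("alignment has zero columns")
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {i} has length {len(row)}, expected {width}"
                )
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("sequence_ids and rows differ in length")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("duplicate sequence identifiers")
        if self.reference_id not in self.sequence_ids:
            raise ValueError(f"reference not found: {self.reference_id!r}")
        if self.column_map is not None and len(self.column_map) != width:
            raise ValueError("column_map length differs from alignment width")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_index(self) -> int:
        return self.sequence_ids.index(self.reference_id)

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_index]

    @property
    def encoded(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_sequences, n_columns).

        Codes 0..19 index :data:`AA_ALPHABET`; gaps and non-standard
        symbols share :data:`GAP_CODE`. Cached after first use.
        """
        cached = self.__dict__.get("_encoded")
        if cached is None:
            lut = np.full(128, GAP_CODE, dtype=np.int8)
            for aa, i in AA_INDEX.items():
                lut[ord(aa)] = i
            mat = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_sequences, self.n_columns)
            cached = lut[mat]
            self.__dict__["_encoded"] = cached
        return cached


@dataclasses.dataclass
class SequenceWeights:
    """Per-sequence redundancy weights from identity clustering.

    Within each cluster the weights are equal and sum to 1 (weight =
    1 / cluster size), so the total weight equals the number of clusters.
    """

    weights: np.ndarray
    cluster_assignment: np.ndarray
    identity_threshold: float

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.cluster_assignment)))


def read_alignment(
    path: str | Path, format: str = "fasta", reference_id: str | None = None
) -> Alignment:
    """Read an alignment from FASTA or Stockholm.

    Characters are uppercased and both ``.`` and ``-`` are normalized to
    ``-``. ``reference_id`` must occur exactly once.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty alignment file: {path}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq).upper().replace(".", GAP) for rec in msa]
    if reference_id is None:
        reference_id = ids[0]
    if ids.count(reference_id) != 1:
        raise ValueError(
            f"reference not found exactly once: {reference_id!r} "
            f"occurs {ids.count(reference_id)} times"
        )
    return Alignment(sequence_ids=ids, rows=rows, reference_id=reference_id)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment to FASTA."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.sequence_ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def trim_alignment(aln: Alignment) -> Alignment:
    """Trim an alignment relative to its reference sequence.

    Applied once, in order: (1) drop columns where the reference has a gap;
    (2) of the remaining columns, drop those with strictly more than 50%
    gaps; (3) drop sequences whose non-gap characters cover strictly less
    than 50% of the trimmed reference length. The reference itself is never
    removed. Idempotent.
    """
    chars = np.array([list(row) for row in aln.rows])
    ref = chars[aln.reference_index]

    keep_cols = ref != GAP
    chars = chars[:, keep_cols]
    if chars.shape[1] == 0:
        raise ValueError("empty alignment after trimming")

    gap_frac = (chars == GAP).mean(axis=0)
    chars = chars[:, gap_frac <= 0.5]
    if chars.shape[1] == 0:
        raise ValueError("empty alignment after trimming")

    width = chars.shape[1]
    coverage = (chars != GAP).sum(axis=1) / width
    keep_rows = coverage >= 0.5
    keep_rows[aln.reference_index] = True

    ids = [sid for sid, k in zip(aln.sequence_ids, keep_rows) if k]
    rows = ["".join(r) for r, k in zip(chars, keep_rows) if k]
    return Alignment(sequence_ids=ids, rows=rows, reference_id=aln.reference_id)


def pairwise_identity_matrix(aln: Alignment) -> np.ndarray:
    """Fraction of identical residues per sequence pair.

    Identity = matches / number of columns where both sequences carry a
    residue; columns where either has a gap (or non-standard symbol) are
    excluded. Pairs sharing no residue columns get identity 0.
    """
    enc = aln.encoded
    nongap = enc < GAP_CODE
    n = aln.n_sequences
    ident = np.eye(n)
    for i in range(n - 1):
        both = nongap[i] & nongap[i + 1 :]
        eq = (enc[i] == enc[i + 1 :]) & both
        denom = both.sum(axis=1)
        frac = np.where(denom > 0, eq.sum(axis=1) / np.maximum(denom, 1), 0.0)
        ident[i, i + 1 :] = frac
        ident[i + 1 :, i] = frac
    return ident


def cluster_weights(aln: Alignment, identity_threshold: float = 0.62) -> SequenceWeights:
    """Single-linkage identity clustering and reciprocal cluster weights.

    Sequences with pairwise identity >= ``identity_threshold`` are joined
    (transitively); each sequence is weighted 1 / (its cluster size), the
    Hobohm-style correction for phylogenetic redundancy.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must lie in (0, 1]")
    ident = pairwise_identity_matrix(aln)
    n = aln.n_sequences

    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.nonzero(np.triu(ident >= identity_threshold, k=1))
    for i, j in zip(ii, jj):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri

    roots = np.array([find(i) for i in range(n)])
    _, labels, counts = np.unique(roots, return_inverse=True, return_counts=True)
    weights = 1.0 / counts[labels]
    return SequenceWeights(
        weights=weights,
        cluster_assignment=labels,
        identity_threshold=identity_threshold,
    )


def map_columns_to_structure(aln: Alignment, structure) -> Alignment:
    """Map alignment columns to structure residues via the reference row.

    Tries an exact substring match between the (gap-free) reference row and
    the structure's one-letter sequence in either direction, falling back to
    a global pairwise alignment. Columns without a structure residue are
    marked unmapped (``None``) and stay invisible to proximity scores.

    Raises ``ValueError`` when fewer than 50% of the reference columns match
    the structure sequence.
    """
    ref = aln.reference_row
    if GAP in ref:
        raise ValueError("reference row contains gaps; trim the alignment first")
    keys = structure.residue_keys()
    sseq = structure.one_letter_sequence()
    width = len(ref)
    col_map: list[Optional[ResidueKey]] = [None] * width

    pos = sseq.find(ref)
    if pos >= 0:
        for c in range(width):
            col_map[c] = keys[pos + c]
        n_match = width
    else:
        pos = ref.find(sseq)
        if pos >= 0:
            for k, key in enumerate(keys):
                col_map[pos + k] = key
            n_match = len(keys)
        else:
            aligner = PairwiseAligner(
                mode="global",
                match_score=2,
                mismatch_score=-1,
                open_gap_score=-5,
                extend_gap_score=-0.5,
            )
            best = aligner.align(ref, sseq)[0]
            n_match = 0
            for (rs, re), (ss, _se) in zip(best.aligned[0], best.aligned[1]):
                for off in range(re - rs):
                    col_map[rs + off] = keys[ss + off]
                    if ref[rs + off] == sseq[ss + off]:
                        n_match += 1
    if n_match < 0.5 * width:
        raise ValueError(
            "reference/structure mismatch: only "
            f"{n_match}/{width} reference columns match the structure sequence"
        )
    return dataclasses.replace(aln, column_map=col_map)
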