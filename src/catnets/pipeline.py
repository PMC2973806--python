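"""End-to-end scoring workflow.

``prepare_family`` runs the expensive, parameter-independent stages once
(trimming, structure mapping, redundancy weights, raw-KL conservation, the
MI matrix with permutation Z-scores, and the residue distance matrix);
``score_table`` then derives the per-residue cMI/pMI/pC/Cls scores for any
parameter set, which is what makes the brute-force grid search affordable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import (
    Alignment,
    ResidueKey,
    SequenceWeights,
    cluster_weights,
    map_columns_to_structure,
    trim_alignment,
)
from .cls import ClsParams, FamilyRecord, cls
from .conservation import conservation_profile, load_background
from .evaluation import EvaluationResult, evaluate
from .mi import MIResult, permutation_zscores
from .structure import (
    DistanceMatrix,
    cumulative_mi,
    proximity_average,
    residue_distance_matrix,
)

logger = logging.getLogger(__name__)


def read_annotation(path, default_chain: str = "A") -> set[ResidueKey]:
    """Read a CSA-style catalytic-residue annotation TSV.

    Accepted rows (comments starting with ``#`` ignored):
    ``chain<TAB>residue_number[<TAB>label]`` or ``residue_number[<TAB>label]``
    (then ``default_chain`` applies). Rows with a label of 0 are skipped.
    """
    keys: set[ResidueKey] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lstrip("-").isdigit():
            chain, number = default_chain, int(fields[0])
            label = fields[1] if len(fields) > 1 else "1"
        else:
            chain, number = fields[0], int(fields[1])
            label = fields[2] if len(fields) > 2 else "1"
        if label.strip() in ("0", "", "no", "false"):
            continue
        keys.add((chain, number, " "))
    if not keys:
        raise ValueError(f"no catalytic residues found in {path}")
    return keys


def load_family(
    alignment_path,
    structure_path,
    annotation_path=None,
    chain: str = "A",
    reference_id: Optional[str] = None,
    alignment_format: str = "fasta",
    model: int = 1,
    identifier: Optional[str] = None,
) -> FamilyRecord:
    """Assemble a FamilyRecord from an alignment, a PDB file and an
    optional catalytic annotation."""
    from .alignment import read_alignment
    from .structure import read_structure

    aln = read_alignment(alignment_path, format=alignment_format, reference_id=reference_id)
    structure = read_structure(structure_path, chain=chain, model=model)
    catalytic = (
        read_annotation(annotation_path, default_chain=chain)
        if annotation_path is not None
        else {structure.residue_keys()[0]}  # placeholder; scoring ignores labels
    )
    record = FamilyRecord(
        alignment=aln,
        structure=structure,
        catalytic_residues=catalytic,
        identifier=identifier or str(Path(alignment_path).parent.name or alignment_path),
    )
    if annotation_path is None:
        record.catalytic_residues = set()
    return record


#: below this many sequences, conservation-based prediction is unreliable
MIN_SEQUENCES = 10
#: below this many sequence clusters, MI estimates are unreliable
MIN_CLUSTERS_FOR_MI = 400


@dataclasses.dataclass
class PreparedFamily:
    """Parameter-independent intermediates for one family."""

    record: FamilyRecord
    alignment: Alignment  # trimmed, with column_map filled
    weights: SequenceWeights
    kl_columns: np.ndarray
    mi: MIResult
    mapped_columns: np.ndarray  # column indices with a structure residue
    residue_keys: list[ResidueKey]  # one per mapped column, in column order
    distance_matrix: DistanceMatrix  # restricted to the mapped residues
    kl_residues: np.ndarray
    labels: Optional[np.ndarray]  # is_catalytic per mapped residue
    warnings: list[str]


def prepare_family(
    record: FamilyRecord,
    n_permutations: int = 100,
    seed: int = 42,
    pseudocount: bool = True,
    background: Optional[np.ndarray] = None,
    conservation_condition: str = "raw",
    null_on: str = "apc",
    per_pair_null: bool = True,
) -> PreparedFamily:
    """Run the parameter-independent pipeline stages for one family.

    Conservation defaults to the raw KL score (the best-performing
    condition); MI always uses redundancy weighting and the low-count
    correction. Deterministic given ``seed``.
    """
    if background is None:
        background = load_background()
    warnings: list[str] = []

    aln = trim_alignment(record.alignment)
    aln = map_columns_to_structure(aln, record.structure)
    if aln.n_sequences < MIN_SEQUENCES:
        msg = (
            f"{record.identifier}: only {aln.n_sequences} sequences after trimming; "
            f"at least {MIN_SEQUENCES} are needed for meaningful predictions"
        )
        warnings.append(msg)
        logger.warning(msg)
    weights = cluster_weights(aln)
    if weights.n_clusters < MIN_CLUSTERS_FOR_MI:
        msg = (
            f"{record.identifier}: {weights.n_clusters} sequence clusters; "
            f"MI estimates are most reliable above {MIN_CLUSTERS_FOR_MI}"
        )
        warnings.append(msg)
        logger.info(msg)

    kl_columns = conservation_profile(
        aln, method="kl", condition=conservation_condition, background=background
    ).scores
    mi = permutation_zscores(
        aln,
        weights=weights,
        pseudocount=pseudocount,
        n_permutations=n_permutations,
        seed=seed,
        background=background,
        null_on=null_on,
        per_pair=per_pair_null,
    )

    mapped = np.array(
        [c for c, key in enumerate(aln.column_map) if key is not None], dtype=int
    )
    residue_keys = [aln.column_map[c] for c in mapped]
    dm_full = residue_distance_matrix(record.structure)
    pos = {key: i for i, key in enumerate(dm_full.residue_keys)}
    sel = np.array([pos[key] for key in residue_keys], dtype=int)
    dm = DistanceMatrix(
        distances=dm_full.distances[np.ix_(sel, sel)], residue_keys=residue_keys
    )

    labels = None
    if record.catalytic_residues:
        labels = np.array(
            [key in record.catalytic_residues for key in residue_keys], dtype=bool
        )
        unmatched = set(record.catalytic_residues) - set(residue_keys)
        if unmatched:
            msg = (
                f"{record.identifier}: catalytic residues not covered by the "
                f"alignment mapping: {sorted(unmatched)}"
            )
            warnings.append(msg)
            logger.warning(msg)

    return PreparedFamily(
        record=record,
        alignment=aln,
        weights=weights,
        kl_columns=kl_columns,
        mi=mi,
        mapped_columns=mapped,
        residue_keys=residue_keys,
        distance_matrix=dm,
        kl_residues=kl_columns[mapped],
        labels=labels,
        warnings=warnings,
    )


def score_table(
    prep: PreparedFamily,
    params: Optional[ClsParams] = None,
    include_self: bool = False,
    normalize_kl: bool = False,
) -> pd.DataFrame:
    """Per-residue score table (KL, cMI, pMI, pC, Cls) for one family.

    Rows are the structure-mapped residues in alignment-column order.
    ``normalize_kl`` min-max rescales the KL term of the Cls sum to [0, 1]
    (a sensitivity analysis; off by default, matching the published score).
    """
    if params is None:
        params = ClsParams()
    cmi = cumulative_mi(prep.mi, params.z_thr)[prep.mapped_columns]
    pmi = proximity_average(
        cmi, prep.distance_matrix, params.d_mi, include_self=include_self
    )
    pc = proximity_average(
        prep.kl_residues, prep.distance_matrix, params.d_c, include_self=include_self
    )
    kl_term = prep.kl_residues
    if normalize_kl:
        lo, hi = kl_term.min(), kl_term.max()
        kl_term = np.zeros_like(kl_term) if hi <= lo else (kl_term - lo) / (hi - lo)
    table = pd.DataFrame(
        {
            "chain": [k[0] for k in prep.residue_keys],
            "residue_number": [k[1] for k in prep.residue_keys],
            "icode": [k[2] for k in prep.residue_keys],
            "column": prep.mapped_columns,
            "kl": prep.kl_residues,
            "cmi": cmi,
            "pmi": pmi,
            "pc": pc,
            "cls": cls(kl_term, pmi, pc, params),
        }
    )
    if prep.labels is not None:
        table["is_catalytic"] = prep.labels
    return table


#: the six rankings compared in the benchmark: each maps a score table and
#: parameter set to a per-residue score vector.
METHOD_SCORES = {
    "KL": lambda t, p: t["kl"].to_numpy(),
    "pMI": lambda t, p: t["pmi"].to_numpy(),
    "pC": lambda t, p: t["pc"].to_numpy(),
    "KL+pMI": lambda t, p: t["kl"].to_numpy() + p.w_mi * t["pmi"].to_numpy(),
    "KL+pC": lambda t, p: t["kl"].to_numpy() + p.w_c * t["pc"].to_numpy(),
    "Cls": lambda t, p: t["cls"].to_numpy(),
}


def evaluate_family(
    prep: PreparedFamily, params: Optional[ClsParams] = None
) -> dict[str, EvaluationResult]:
    """Evaluate the six method rankings on one annotated family."""
    if prep.labels is None:
        raise ValueError(f"{prep.record.identifier}: no catalytic annotation")
    if params is None:
        params = ClsParams()
    table = score_table(prep, params)
    labels = prep.labels
    return {
        name: evaluate(fn(table, params), labels) for name, fn in METHOD_SCORES.items()
    }


def evaluation_report(
    prepared: list[PreparedFamily], params: Optional[ClsParams] = None
) -> pd.DataFrame:
    """Tidy per-family evaluation (one row per family x method) plus averages.

    Families that cannot be evaluated (no positives among the mapped
    residues) are skipped with a warning.
    """
    if params is None:
        params = ClsParams()
    rows = []
    for prep in prepared:
        if prep.labels is None or not prep.labels.any() or prep.labels.all():
            logger.warning(
                "%s: skipped (no usable positive/negative labels)",
                prep.record.identifier,
            )
            continue
        for name, result in evaluate_family(prep, params).items():
            rows.append(
                {
                    "family": prep.record.identifier,
                    "method": name,
                    "auc": result.auc,
                    "auc01": result.auc01,
                    "sens@0.99": result.sensitivities_at[0.99],
                    "sens@0.95": result.sensitivities_at[0.95],
                    "sens@0.90": result.sensitivities_at[0.90],
                    "sens@0.85": result.sensitivities_at[0.85],
                    "threshold@0.90": result.thresholds_at[0.90],
                    "n_positive": result.n_positive,
                    "n_negative": result.n_negative,
                }
            )
    report = pd.DataFrame(rows)
    if report.empty:
        raise ValueError("no family could be evaluated")
    means = (
        report.groupby("method", sort=False)
        .mean(numeric_only=True)
        .reset_index()
        .assign(family="AVERAGE")
    )
    return pd.concat([report, means], ignore_index=True)
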