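"""Pairwise mutual information between alignment columns.

The pipeline is: weighted joint amino-acid pair frequencies (sequences
gapped at either column are excluded and the weights renormalized over the
rest) -> MI in bits -> average product correction (APC) to strip the
background/phylogenetic component -> permutation Z-scores against a null
built from column-shuffled alignments.

All matrices are symmetric with a NaN diagonal (MI of a column with itself
is excluded everywhere downstream).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np

from .alignment import Alignment, GAP_CODE, SequenceWeights
from .conservation import N_AA, load_background, pseudocount_weight

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MIResult:
    """Raw, APC-corrected and Z-scored MI matrices for one alignment."""

    mi_raw: np.ndarray
    mi_apc: np.ndarray
    zscores: np.ndarray
    n_permutations: int
    seed: int

    @property
    def n_columns(self) -> int:
        return self.mi_raw.shape[0]


def _onehot(enc: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted and unweighted one-hot encodings, shape (n_seq, n_col*20).

    Gap rows are all-zero, which makes every joint count below automatically
    restricted to sequences ungapped at both columns.
    """
    n_seq, n_col = enc.shape
    x = np.zeros((n_seq, n_col * N_AA))
    rows, cols = np.nonzero(enc < GAP_CODE)
    x[rows, cols * N_AA + enc[rows, cols]] = 1.0
    return x * w[:, None], x


def _mi_from_counts(
    counts: np.ndarray,
    pair_weight: np.ndarray,
    pseudocount: bool,
    beta: float,
    background: np.ndarray,
) -> np.ndarray:
    """MI matrix from a (n_col, n_col, 20, 20) joint count tensor."""
    n_col = counts.shape[0]
    if pseudocount:
        qq = np.outer(background, background)
        counts = counts + beta * qq[None, None, :, :]
        pair_weight = pair_weight + beta
    zero = pair_weight <= 0
    if np.any(zero[np.triu_indices(n_col, k=1)]):
        logger.warning(
            "column pairs with zero joint weight; their MI is masked to 0"
        )
    denom = np.where(zero, 1.0, pair_weight)
    p = counts / denom[:, :, None, None]
    pa = p.sum(axis=3)  # marginal of the first column within the pair
    pb = p.sum(axis=2)
    prod = pa[:, :, :, None] * pb[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / np.where(prod > 0, prod, 1.0), 1.0)
        mi = (np.where(p > 0, p, 0.0) * np.log2(ratio)).sum(axis=(2, 3))
    mi[zero] = 0.0
    np.fill_diagonal(mi, np.nan)
    return mi


def _pair_mi_encoded(
    enc: np.ndarray,
    w: np.ndarray,
    pseudocount: bool,
    beta: float,
    background: np.ndarray,
) -> np.ndarray:
    n_col = enc.shape[1]
    xw, x = _onehot(enc, w)
    big = xw.T @ x  # (n_col*20, n_col*20) joint weighted counts
    counts = big.reshape(n_col, N_AA, n_col, N_AA).transpose(0, 2, 1, 3)
    pair_weight = counts.sum(axis=(2, 3))
    return _mi_from_counts(counts, pair_weight, pseudocount, beta, background)


def pair_mi(
    aln: Alignment,
    weights: Optional[SequenceWeights] = None,
    pseudocount: bool = True,
    background: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Symmetric matrix of column-pair mutual information in bits.

    For each pair (i, j) the joint frequencies are accumulated over the
    sequences carrying residues at both columns, weighted by the redundancy
    weights and optionally blended with the product-of-background
    pseudocount; MI_ij = sum_ab p_ab log2(p_ab / (p_a p_b)) with the
    marginals taken from the joint. Diagonal is NaN.
    """
    if aln.n_columns < 2:
        raise ValueError("mutual information needs at least 2 columns")
    if background is None:
        background = load_background()
    w = (
        np.ones(aln.n_sequences)
        if weights is None
        else np.asarray(weights.weights, dtype=float)
    )
    beta = pseudocount_weight(weights, aln.n_sequences)
    return _pair_mi_encoded(aln.encoded, w, pseudocount, beta, background)


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average product correction of Dunn et al.

    corrected_ij = MI_ij - (mean_i * mean_j) / overall_mean, with mean_i the
    average MI of column i to all other columns and overall_mean the average
    over all pairs. If the overall mean is 0 there is nothing to correct and
    the input is returned unchanged.
    """
    mi = np.asarray(mi, dtype=float)
    if mi.ndim != 2 or mi.shape[0] != mi.shape[1]:
        raise ValueError("APC needs a square matrix")
    if mi.shape[0] < 3:
        raise ValueError("APC needs at least 3 columns")
    work = mi.copy()
    np.fill_diagonal(work, np.nan)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(work, axis=1)
        overall = np.nanmean(work)
    if not np.isfinite(overall) or overall == 0:
        return work
    corrected = work - np.outer(col_mean, col_mean) / overall
    np.fill_diagonal(corrected, np.nan)
    return corrected


def write_mi_tsv(result: MIResult, path) -> None:
    """Write the upper-triangle (col_i, col_j, mi_raw, mi_apc, z) triplets."""
    iu = np.triu_indices(result.n_columns, k=1)
    with open(path, "w") as fh:
        fh.write("col_i\tcol_j\tmi_raw\tmi_apc\tz\n")
        for i, j in zip(*iu):
            fh.write(
                f"{i}\t{j}\t{result.mi_raw[i, j]:.6g}\t"
                f"{result.mi_apc[i, j]:.6g}\t{result.zscores[i, j]:.6g}\n"
            )


def _shuffle_within_columns(
    enc: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute residues within each column, leaving gap positions fixed."""
    out = enc.copy()
    for c in range(enc.shape[1]):
        idx = np.nonzero(enc[:, c] < GAP_CODE)[0]
        if idx.size > 1:
            out[idx, c] = enc[rng.permutation(idx), c]
    return out


def permutation_zscores(
    aln: Alignment,
    weights: Optional[SequenceWeights] = None,
    pseudocount: bool = True,
    n_permutations: int = 100,
    seed: int = 42,
    background: Optional[np.ndarray] = None,
    null_on: str = "apc",
    per_pair: bool = True,
) -> MIResult:
    """APC-corrected MI matrix with permutation Z-scores.

    The null distribution is built by shuffling residues within columns
    (which preserves every column's composition but destroys covariation)
    and recomputing the APC-corrected MI (``null_on='raw'`` skips the APC
    step in the null). By default each pair is standardized against its own
    permuted values; ``per_pair=False`` pools all pairs from all
    permutations into one global null per alignment, which is cheaper to
    justify statistically but mixes the very different small-sample MI
    biases of heterogeneous column pairs into one spread and so buries
    genuine covariation. Deterministic given ``seed``.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be at least 20")
    if null_on not in ("apc", "raw"):
        raise ValueError("null_on must be 'apc' or 'raw'")
    if background is None:
        background = load_background()
    enc = aln.encoded
    w = (
        np.ones(aln.n_sequences)
        if weights is None
        else np.asarray(weights.weights, dtype=float)
    )
    beta = pseudocount_weight(weights, aln.n_sequences)

    mi_raw = _pair_mi_encoded(enc, w, pseudocount, beta, background)
    mi_apc = apc_correct(mi_raw)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(aln.n_columns, k=1)
    null_values = np.empty((n_permutations, iu[0].size))
    for p in range(n_permutations):
        shuffled = _shuffle_within_columns(enc, rng)
        null_mi = _pair_mi_encoded(shuffled, w, pseudocount, beta, background)
        if null_on == "apc":
            null_mi = apc_correct(null_mi)
        null_values[p] = null_mi[iu]

    observed = mi_apc if null_on == "apc" else mi_raw
    if per_pair:
        mu = null_values.mean(axis=0)
        sd = null_values.std(axis=0, ddof=0)
    else:
        mu = np.full(iu[0].size, null_values.mean())
        sd = np.full(iu[0].size, null_values.std(ddof=0))

    flat_obs = observed[iu]
    degenerate = sd <= 0
    if np.any(degenerate):
        logger.warning(
            "%d pairs have a degenerate (zero-spread) null; Z masked", int(degenerate.sum())
        )
    z_flat = np.where(degenerate, np.nan, (flat_obs - mu) / np.where(degenerate, 1.0, sd))
    z = np.full_like(mi_raw, np.nan)
    z[iu] = z_flat
    z[(iu[1], iu[0])] = z_flat
    return MIResult(
        mi_raw=mi_raw,
        mi_apc=mi_apc,
        zscores=z,
        n_permutations=n_permutations,
        seed=seed,
    )
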