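"""Per-column conservation scores.

Three measures — maximal frequency, Shannon entropy and Kullback-Leibler
relative entropy against an amino-acid background — each computable under
four correction conditions:

``raw``
    plain frequencies;
``c``
    sequence weighting by 62% identity clustering;
``l``
    low-count (pseudocount) correction blending the column frequencies with
    the background;
``cl``
    both corrections.

All scores are in bits and oriented so that higher = more conserved. The
Shannon measure is reported as ``log2(20) - H`` for that reason.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .alignment import AA_ALPHABET, AA_INDEX, GAP_CODE, Alignment, SequenceWeights, cluster_weights

N_AA = 20
LOG2_20 = float(np.log2(N_AA))

CONDITIONS = ("raw", "c", "l", "cl")
METHODS = ("max_freq", "shannon", "kl")


def load_background(path: str | Path | None = None) -> np.ndarray:
    """Load a 20-entry amino-acid background distribution.

    Reads the bundled UniProtKB/Swiss-Prot composition by default, or any
    TSV with one ``<one-letter>\\t<frequency>`` line per amino acid.
    Frequencies are renormalized to sum to 1 and must all be positive.
    """
    if path is None:
        source = resources.files("catnets").joinpath("data/background_frequencies.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    freqs = np.zeros(N_AA)
    seen = set()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, value = line.split("\t")
        if aa not in AA_INDEX:
            raise ValueError(f"unknown amino acid in background table: {aa!r}")
        freqs[AA_INDEX[aa]] = float(value)
        seen.add(aa)
    if len(seen) != N_AA:
        raise ValueError(f"background table covers {len(seen)}/20 amino acids")
    if np.any(freqs <= 0):
        raise ValueError("background frequencies must be strictly positive")
    return freqs / freqs.sum()


@dataclasses.dataclass
class ColumnProfile:
    """Per-column amino-acid frequencies plus effective counts.

    ``frequencies`` has shape (n_columns, 20) and each row sums to 1 over
    the 20 standard amino acids; gaps and non-standard symbols never count.
    ``effective_counts`` is the weighted number of residues per column.
    """

    frequencies: np.ndarray
    effective_counts: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("column frequencies must sum to 1")
        if np.any(self.frequencies < 0):
            raise ValueError("negative column frequency")


@dataclasses.dataclass
class ConservationProfile:
    """One conservation score per alignment column; higher = more conserved."""

    scores: np.ndarray
    method: str
    condition: str


def pseudocount_weight(weights: Optional[SequenceWeights], n_sequences: int) -> float:
    """Strength of the background blend used by the low-count correction.

    The number of sequence clusters when weighting is active, else
    sqrt(n_sequences) — in both cases an effective-sample-size scale.
    """
    if weights is not None:
        return float(weights.n_clusters)
    return float(np.sqrt(n_sequences))


def column_frequencies(
    aln: Alignment,
    weights: Optional[SequenceWeights] = None,
    pseudocount: bool = False,
    background: Optional[np.ndarray] = None,
) -> ColumnProfile:
    """Weighted per-column amino-acid frequencies, optionally pseudocounted.

    The pseudocount blend is ``p' = (n_eff * p + beta * q) / (n_eff + beta)``
    with ``q`` the background and ``beta`` from :func:`pseudocount_weight`.
    A column carrying zero residue weight is an error.
    """
    if background is None:
        background = load_background()
    enc = aln.encoded
    n_seq, n_col = enc.shape
    if weights is not None and len(weights.weights) != n_seq:
        raise ValueError("weights do not match the number of sequences")
    w = np.ones(n_seq) if weights is None else np.asarray(weights.weights, dtype=float)

    counts = np.zeros((n_col, N_AA))
    for c in range(n_col):
        codes = enc[:, c]
        ok = codes < GAP_CODE
        counts[c] = np.bincount(codes[ok], weights=w[ok], minlength=N_AA)
    n_eff = counts.sum(axis=1)
    empty = np.nonzero(n_eff <= 0)[0]
    if empty.size:
        raise ValueError(f"column {int(empty[0])} has zero non-gap weight")
    freqs = counts / n_eff[:, None]
    if pseudocount:
        beta = pseudocount_weight(weights, n_seq)
        freqs = (n_eff[:, None] * freqs + beta * background[None, :]) / (
            n_eff[:, None] + beta
        )
    return ColumnProfile(frequencies=freqs, effective_counts=n_eff, background=background)


def max_frequency(profile: ColumnProfile) -> np.ndarray:
    """Frequency of the most represented amino acid, per column."""
    return profile.frequencies.max(axis=1)


def shannon_conservation(profile: ColumnProfile) -> np.ndarray:
    """log2(20) minus the Shannon entropy of each column (bits)."""
    p = profile.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return LOG2_20 + terms.sum(axis=1)


def kl_conservation(profile: ColumnProfile) -> np.ndarray:
    """Kullback-Leibler relative entropy of each column vs the background."""
    p = profile.frequencies
    q = profile.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / q), 0.0)
    return terms.sum(axis=1)


_MEASURES = {
    "max_freq": max_frequency,
    "shannon": shannon_conservation,
    "kl": kl_conservation,
}


def conservation_profile(
    aln: Alignment,
    method: str = "kl",
    condition: str = "raw",
    background: Optional[np.ndarray] = None,
    identity_threshold: float = 0.62,
) -> ConservationProfile:
    """One of the twelve (measure x condition) conservation scores."""
    if method not in _MEASURES:
        raise ValueError(f"unknown conservation method: {method!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition!r}")
    weights = cluster_weights(aln, identity_threshold) if "c" in condition else None
    profile = column_frequencies(
        aln, weights=weights, pseudocount="l" in condition, background=background
    )
    return ConservationProfile(
        scores=_MEASURES[method](profile), method=method, condition=condition
    )
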