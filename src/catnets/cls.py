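"""The combined catalytic likeliness score (Cls) and its parameter fit.

Cls ranks residues by a weighted sum of three per-residue signals:

    Cls = KL + w_mi * pMI + w_c * pC

with KL the (unnormalized, bits) Kullback-Leibler conservation, pMI and pC
the [0,1] proximity averages of cumulative MI and conservation, and the KL
term carrying a fixed weight of 1 — w_mi and w_c are weights relative to
it. Only relative weights affect the ranking (and hence the AUC).

Five free parameters govern the score: the MI Z-score threshold feeding
cMI, the two proximity distance thresholds, and the two weights. They are
fitted by brute-force grid search under family-level five-fold cross
validation, maximizing the mean per-family AUC on the training folds.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, ResidueKey
from .evaluation import auc_rows
from .structure import Structure, cumulative_mi, proximity_average

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClsParams:
    """The five free parameters of the catalytic likeliness score.

    Defaults are the published cross-validated optima.
    """

    z_thr: float = 5.5
    d_mi: float = 8.0
    d_c: float = 5.6
    w_mi: float = 0.6
    w_c: float = 0.2

    def __post_init__(self) -> None:
        if self.d_mi <= 0 or self.d_c <= 0:
            raise ValueError("distance thresholds must be positive")
        if self.w_mi < 0 or self.w_c < 0:
            raise ValueError("weights must be non-negative")

    def astuple(self) -> tuple[float, float, float, float, float]:
        return (self.z_thr, self.d_mi, self.d_c, self.w_mi, self.w_c)


@dataclasses.dataclass
class FamilyRecord:
    """One benchmark family: alignment + structure + catalytic annotation."""

    alignment: Alignment
    structure: Structure
    catalytic_residues: set[ResidueKey]
    identifier: str = "family"

    def __post_init__(self) -> None:
        if not self.catalytic_residues:
            raise ValueError(f"{self.identifier}: no catalytic residues annotated")
        known = set(self.structure.residue_keys())
        missing = set(self.catalytic_residues) - known
        if missing:
            raise ValueError(
                f"{self.identifier}: catalytic residues absent from structure: {sorted(missing)}"
            )


def cls(kl, pmi, pc, params: ClsParams):
    """Combine the three per-residue scores into the Cls ranking score.

    Accepts plain arrays (positionally aligned) or pandas Series indexed by
    residue; Series with mismatched residue sets raise an error naming the
    symmetric difference.
    """
    if isinstance(kl, pd.Series) or isinstance(pmi, pd.Series) or isinstance(pc, pd.Series):
        kl, pmi, pc = pd.Series(kl), pd.Series(pmi), pd.Series(pc)
        sets = [set(s.index) for s in (kl, pmi, pc)]
        union = set.union(*sets)
        inter = set.intersection(*sets)
        if union != inter:
            raise ValueError(
                f"mismatched residue sets; symmetric difference: {sorted(union - inter)}"
            )
        pmi, pc = pmi.reindex(kl.index), pc.reindex(kl.index)
    else:
        kl, pmi, pc = (np.asarray(v, dtype=float) for v in (kl, pmi, pc))
        if not (kl.shape == pmi.shape == pc.shape):
            raise ValueError("score vectors differ in length")
    return kl + params.w_mi * pmi + params.w_c * pc


@dataclasses.dataclass
class ParamGrid:
    """Axis values for the brute-force parameter search."""

    z_thr: np.ndarray
    d_mi: np.ndarray
    d_c: np.ndarray
    w_mi: np.ndarray
    w_c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("z_thr", "d_mi", "d_c", "w_mi", "w_c"):
            values = np.sort(np.unique(np.asarray(getattr(self, name), dtype=float)))
            if values.size == 0:
                raise ValueError(f"empty grid axis: {name}")
            setattr(self, name, values)

    @property
    def size(self) -> int:
        return (
            self.z_thr.size * self.d_mi.size * self.d_c.size * self.w_mi.size * self.w_c.size
        )


def default_grid() -> ParamGrid:
    """Grid bracketing the published optima: Z 4-8, distances 4-12 A, weights 0-1.5."""
    return ParamGrid(
        z_thr=np.arange(4.0, 8.01, 0.5),
        d_mi=np.arange(4.0, 12.01, 1.0),
        d_c=np.arange(4.0, 12.01, 1.0),
        w_mi=np.arange(0.0, 1.501, 0.1),
        w_c=np.arange(0.0, 1.501, 0.1),
    )


@dataclasses.dataclass
class GridSearchResult:
    """Per-fold fitted parameters and held-out performance."""

    fold_params: list[ClsParams]
    fold_auc: list[float]
    mean_params: ClsParams
    std_params: dict[str, float]
    folds: list[list[int]]


def _family_auc_grid(prep, grid: ParamGrid) -> Optional[np.ndarray]:
    """AUC of Cls on one prepared family for every grid point.

    Returns an array of shape (n_z, n_dmi, n_dc, n_wmi, n_wc), or None when
    the family cannot be scored (e.g. a single-class label vector).
    """
    labels = prep.labels
    if labels is None or labels.all() or not labels.any():
        return None
    kl = prep.kl_residues
    weight_pairs = np.array(list(itertools.product(grid.w_mi, grid.w_c)))
    out = np.empty(
        (grid.z_thr.size, grid.d_mi.size, grid.d_c.size, grid.w_mi.size, grid.w_c.size)
    )
    pc_by_dc = [
        proximity_average(kl, prep.distance_matrix, dc) for dc in grid.d_c
    ]
    for iz, z in enumerate(grid.z_thr):
        cmi = cumulative_mi(prep.mi, z)[prep.mapped_columns]
        for idm, dmi in enumerate(grid.d_mi):
            pmi = proximity_average(cmi, prep.distance_matrix, dmi)
            for idc in range(grid.d_c.size):
                scores = (
                    kl[None, :]
                    + weight_pairs[:, 0:1] * pmi[None, :]
                    + weight_pairs[:, 1:2] * pc_by_dc[idc][None, :]
                )
                out[iz, idm, idc] = auc_rows(scores, labels).reshape(
                    grid.w_mi.size, grid.w_c.size
                )
    return out


def _argmax_lexicographic(acc: np.ndarray) -> tuple[int, ...]:
    # np.argmax returns the first maximum in C order; with ascending-sorted
    # axes ordered (z, d_mi, d_c, w_mi, w_c) that is the lexicographically
    # smallest tied parameter set.
    return np.unravel_index(int(np.argmax(acc)), acc.shape)


def grid_search_cv(
    families: Sequence,
    grid: Optional[ParamGrid] = None,
    n_folds: int = 5,
    seed: int = 0,
    n_permutations: int = 100,
    prepared: Optional[Sequence] = None,
) -> GridSearchResult:
    """Five-fold cross-validated brute-force fit of the Cls parameters.

    Families (never residues) are split into ``n_folds`` seeded random
    folds; for each fold the full grid is evaluated on the remaining
    families, maximizing the mean per-family AUC, and the winning point is
    scored on the held-out fold. Ties break toward the lexicographically
    smallest (z_thr, d_mi, d_c, w_mi, w_c).

    ``families`` may be FamilyRecord objects (prepared internally with
    ``n_permutations`` and a per-family seed derived from ``seed``) or
    pre-prepared families may be passed via ``prepared``.
    """
    from .pipeline import prepare_family  # deferred: pipeline imports this module

    if grid is None:
        grid = default_grid()
    if prepared is None:
        prepared = [
            prepare_family(fam, n_permutations=n_permutations, seed=seed + 1000 + i)
            for i, fam in enumerate(families)
        ]
    n_fam = len(prepared)
    if n_fam < n_folds:
        raise ValueError(f"need at least {n_folds} families, got {n_fam}")

    per_family = []
    usable = []
    for i, prep in enumerate(prepared):
        arr = _family_auc_grid(prep, grid)
        if arr is None:
            logger.warning("family %d cannot be scored; skipped", i)
            continue
        per_family.append(arr)
        usable.append(i)
    if not per_family:
        raise ValueError("no family could be scored")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usable))
    folds = [sorted(usable[j] for j in order[k::n_folds]) for k in range(n_folds)]

    total = np.sum(per_family, axis=0)
    by_index = dict(zip(usable, per_family))

    fold_params, fold_auc = [], []
    for fold in folds:
        test_arrays = [by_index[i] for i in fold]
        train_sum = total - (np.sum(test_arrays, axis=0) if test_arrays else 0.0)
        n_train = len(usable) - len(fold)
        if n_train == 0:
            raise ValueError("a fold left no training families")
        idx = _argmax_lexicographic(train_sum)
        params = ClsParams(
            z_thr=float(grid.z_thr[idx[0]]),
            d_mi=float(grid.d_mi[idx[1]]),
            d_c=float(grid.d_c[idx[2]]),
            w_mi=float(grid.w_mi[idx[3]]),
            w_c=float(grid.w_c[idx[4]]),
        )
        fold_params.append(params)
        if test_arrays:
            fold_auc.append(float(np.mean([a[idx] for a in test_arrays])))
        else:
            fold_auc.append(float("nan"))

    stacked = np.array([p.astuple() for p in fold_params])
    mean_params = ClsParams(*[float(v) for v in stacked.mean(axis=0)])
    std = stacked.std(axis=0, ddof=0)
    std_params = dict(zip(("z_thr", "d_mi", "d_c", "w_mi", "w_c"), (float(v) for v in std)))
    return GridSearchResult(
        fold_params=fold_params,
        fold_auc=fold_auc,
        mean_params=mean_params,
        std_params=std_params,
        folds=folds,
    )
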