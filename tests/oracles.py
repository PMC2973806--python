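"""Independent brute-force reference implementations.

Deliberately written in the most literal way possible (dictionaries and
explicit loops over sequences, pairs and cutoffs) so they share no code
path with the package internals they are used to check.
"""

from __future__ import annotations

import itertools
import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def column_freqs_brute(rows, col, weights=None, beta=0.0, background=None):
    weights = [1.0] * len(rows) if weights is None else list(weights)
    counts = {a: 0.0 for a in AA}
    total = 0.0
    for row, w in zip(rows, weights):
        ch = row[col]
        if ch in counts:
            counts[ch] += w
            total += w
    freqs = {a: c / total for a, c in counts.items()}
    if beta > 0:
        freqs = {
            a: (total * freqs[a] + beta * background[a]) / (total + beta) for a in AA
        }
    return freqs


def mi_brute(rows, i, j, weights=None, beta=0.0, background=None):
    """Mutual information of columns i, j by explicit pair counting."""
    weights = [1.0] * len(rows) if weights is None else list(weights)
    joint = {(a, b): 0.0 for a in AA for b in AA}
    total = 0.0
    for row, w in zip(rows, weights):
        a, b = row[i], row[j]
        if a in AA and b in AA:
            joint[(a, b)] += w
            total += w
    if total == 0 and beta == 0:
        return 0.0
    if beta > 0:
        joint = {
            (a, b): joint[(a, b)] + beta * background[a] * background[b]
            for a in AA
            for b in AA
        }
        total = total + beta
    p = {k: v / total for k, v in joint.items()}
    pa = {a: sum(p[(a, b)] for b in AA) for a in AA}
    pb = {b: sum(p[(a, b)] for a in AA) for b in AA}
    mi = 0.0
    for a in AA:
        for b in AA:
            if p[(a, b)] > 0:
                mi += p[(a, b)] * math.log2(p[(a, b)] / (pa[a] * pb[b]))
    return mi


def apc_brute(mat):
    """APC correction by explicit means over off-diagonal entries."""
    n = len(mat)
    means = []
    for i in range(n):
        vals = [mat[i][j] for j in range(n) if j != i]
        means.append(sum(vals) / len(vals))
    allvals = [mat[i][j] for i in range(n) for j in range(n) if j != i]
    overall = sum(allvals) / len(allvals)
    out = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i][j] = mat[i][j] - means[i] * means[j] / overall
    return out


def cmi_brute(apc, z, z_thr):
    n = len(apc)
    cmi = [0.0] * n
    for i in range(n):
        for j in range(n):
            if i != j and z[i][j] >= z_thr:
                cmi[i] += apc[i][j]
    return cmi


def proximity_brute(values, dist, threshold, normalize=True):
    n = len(values)
    avg = []
    for r in range(n):
        neigh = [values[s] for s in range(n) if s != r and 0 < dist[r][s] <= threshold]
        avg.append(sum(neigh) / len(neigh) if neigh else 0.0)
    if not normalize:
        return avg
    lo, hi = min(avg), max(avg)
    if hi <= lo:
        return [0.0] * n
    return [(a - lo) / (hi - lo) for a in avg]


def auc_brute(scores, labels):
    """ROC AUC by exhaustive positive-negative pair counting (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            total += 1.0
        elif p == q:
            total += 0.5
    return total / (len(pos) * len(neg))


def sensitivity_brute(scores, labels, specificity):
    """Max sensitivity over all cutoffs with specificity >= the target."""
    best = 0.0
    for cut in sorted(set(scores)) + [max(scores) + 1.0]:
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= cut)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= cut)
        n_pos = sum(labels)
        n_neg = len(labels) - n_pos
        spec = 1.0 - fp / n_neg
        if spec >= specificity:
            best = max(best, tp / n_pos)
    return best
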