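"""Vectorised pairwise kernels over integer-coded alignments.

Sequences are coded as uint8 with A=0, C=1, G=2, T=3, gap=4, N=5.  All
all-pairs counts are obtained from one-hot matrix products, which keeps the
bootstrap (hundreds of matrix rebuilds) fast without any compiled extension.

Two comparability conventions coexist deliberately:

* *pairwise deletion* — columns where either sequence carries a gap or an N
  are dropped for that pair (used for K2P and percent similarity);
* *raw difference counts* — a base opposite a gap counts as one difference,
  only N columns are dropped (used for mean pairwise differences, Nei
  within/between tables and Fst).
"""

from __future__ import annotations

import numpy as np

A, C, G, T, GAP, N = 0, 1, 2, 3, 4, 5
BASE_CODES = (A, C, G, T)

_TS_PAIRS = ((A, G), (C, T))  # purine/purine and pyrimidine/pyrimidine


def _onehot(arr: np.ndarray, code: int) -> np.ndarray:
    return (arr == code).astype(np.float64)


def comparable_counts(arr: np.ndarray) -> np.ndarray:
    """Pairwise counts of columns where both sequences carry a base."""
    b = (arr < GAP).astype(np.float64)
    return b @ b.T


def transition_transversion_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(comparable, transitions, transversions) count matrices.

    Counts are over base-vs-base columns only (pairwise deletion).
    """
    oh = {c: _onehot(arr, c) for c in BASE_CODES}
    comparable = comparable_counts(arr)
    same = sum(oh[c] @ oh[c].T for c in BASE_CODES)
    ts = sum(oh[a] @ oh[b].T + oh[b] @ oh[a].T for a, b in _TS_PAIRS)
    diff = comparable - same
    tv = diff - ts
    return comparable, ts, tv


def k2p_matrix(arr: np.ndarray) -> np.ndarray:
    """Kimura two-parameter distances for all pairs.

    Saturated pairs (a log argument <= 0) come back as +inf; pairs with no
    comparable columns come back as NaN — the caller decides whether either
    is an error.
    """
    comparable, ts, tv = transition_transversion_counts(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / comparable
        Q = tv / comparable
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    d = np.where((w1 <= 0) | (w2 <= 0), np.inf, d)
    d = np.where(comparable == 0, np.nan, d)
    np.fill_diagonal(d, 0.0)
    return d


def p_distance_matrix(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p, comparable): proportion of differing comparable columns per pair.

    NaN where a pair has no comparable columns.
    """
    comparable, ts, tv = transition_transversion_counts(arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (ts + tv) / comparable
    np.fill_diagonal(p, 0.0)
    return p, comparable


def raw_difference_matrix(arr: np.ndarray) -> np.ndarray:
    """Pairwise counts of differing columns, base-vs-gap included.

    Columns where either sequence has N are excluded for that pair;
    gap-vs-gap is not a difference.  Values are exact integers in float64.
    """
    valid = (arr != N).astype(np.float64)
    valid_pairs = valid @ valid.T
    same = sum(_onehot(arr, c) @ _onehot(arr, c).T for c in (A, C, G, T, GAP))
    diff = valid_pairs - same
    np.fill_diagonal(diff, 0.0)
    return diff
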