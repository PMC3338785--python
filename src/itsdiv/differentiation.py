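"""Pairwise Fst between populations with permutation significance.

Two estimators operate on the same raw pairwise difference counts:

``nei_ratio``
    Fst = 1 - H_w / H_b, where H_w is the unweighted mean of the two
    within-population average pairwise differences and H_b the average
    difference count over all cross-population pairs.

``amova``
    The two-population variance-component decomposition used by
    population-genetics packages: the difference counts serve as squared
    distances in a sum-of-squared-deviations (SSD) partition, giving
    sigma2_a (among) and sigma2_w (within) with
    n' = N - (n1^2 + n2^2) / N, and Fst = sigma2_a / (sigma2_a + sigma2_w).

Point estimates are clamped to [0, 1] for reporting; the raw value is
retained.  Significance is assessed by reassigning individuals between
the two populations with sizes preserved.  When the number of distinct
assignments C(N, n1) is small enough to enumerate within the permutation
budget, the test is exact (so a 2-vs-2 pair can never fall below
p = 1/3); otherwise a Monte-Carlo test with the add-one correction
p = (1 + #{Fst_perm >= Fst_obs}) / (n_permutations + 1) is used.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from math import comb

import numpy as np

from .errors import ParameterError, ValidationError
from .seq_io import Alignment
from .site_stats import raw_difference_matrix

logger = logging.getLogger(__name__)

ESTIMATORS = ("nei_ratio", "amova")

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class FstMatrix:
    """Pairwise Fst values, raw (unclamped) values, and optional p-values."""

    populations: tuple[str, ...]
    fst: np.ndarray
    fst_raw: np.ndarray
    estimator: str
    p_values: np.ndarray | None = None
    n_permutations: int | None = None
    flags: dict = None

    def pair(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.fst[i, j])

    def p_value(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.p_values[i, j])


def _within_mean(d: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) < 2:
        return 0.0
    block = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(block[iu].mean())


def _within_sum(d: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) < 2:
        return 0.0
    block = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(block[iu].sum())


def fst_from_distances(
    d: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, estimator: str = "nei_ratio"
) -> tuple[float, float, str]:
    """(clamped Fst, raw Fst, flag) for one population pair on a pairwise
    difference-count matrix.  Exposed so independent oracles can drive it
    with engineered matrices."""
    if estimator not in ESTIMATORS:
        raise ParameterError(f"unknown Fst estimator {estimator!r}")
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    flag = ""
    if estimator == "nei_ratio":
        hw = 0.5 * (_within_mean(d, idx_a) + _within_mean(d, idx_b))
        hb = float(d[np.ix_(idx_a, idx_b)].mean())
        if hb == 0.0:
            return 0.0, 0.0, "degenerate:H_b=0"
        raw = 1.0 - hw / hb
    else:
        n1, n2 = len(idx_a), len(idx_b)
        N = n1 + n2
        sum_within = _within_sum(d, idx_a) + _within_sum(d, idx_b)
        sum_cross = float(d[np.ix_(idx_a, idx_b)].sum())
        # SSD over the pooled sample and within groups, difference counts
        # acting as squared distances
        ssd_total = (sum_within + sum_cross) / N
        ssd_within = (_within_sum(d, idx_a) / n1 if n1 else 0.0) + (
            _within_sum(d, idx_b) / n2 if n2 else 0.0
        )
        ssd_among = ssd_total - ssd_within
        df_within = N - 2
        sigma_w = ssd_within / df_within if df_within > 0 else 0.0
        n_prime = N - (n1 * n1 + n2 * n2) / N
        sigma_a = (ssd_among - sigma_w) / n_prime
        denom = sigma_a + sigma_w
        if denom == 0.0:
            return 0.0, 0.0, "degenerate:zero-variance"
        raw = sigma_a / denom
    clamped = min(max(raw, 0.0), 1.0)
    if raw < 0:
        flag = "clamped-negative"
        logger.info("clamped negative Fst %.6g to 0", raw)
    return clamped, raw, flag


def _group_indices(partition, ids):
    pos = {s: k for k, s in enumerate(ids)}
    return {p: np.array([pos[s] for s in members])
            for p, members in partition.groups.items()}


def pairwise_fst(aln: Alignment, partition, estimator: str = "nei_ratio") -> FstMatrix:
    """All-pairs Fst point estimates for the populations of ``partition``.

    Populations of a single isolate contribute a within-distance of 0
    (flagged ``n=1``).
    """
    if estimator not in ESTIMATORS:
        raise ParameterError(f"unknown Fst estimator {estimator!r}")
    pops = tuple(partition.groups)
    if not pops:
        raise ValidationError("partition has no populations")
    ids, d = raw_difference_matrix(aln, list(partition.members()))
    idx = _group_indices(partition, ids)
    k = len(pops)
    fst = np.zeros((k, k))
    raw = np.zeros((k, k))
    flags: dict = {}
    for i, a in enumerate(pops):
        if len(idx[a]) < 2:
            flags[(a,)] = "n=1"
        for j in range(i + 1, k):
            b = pops[j]
            f, r, flag = fst_from_distances(d, idx[a], idx[b], estimator)
            fst[i, j] = fst[j, i] = f
            raw[i, j] = raw[j, i] = r
            if flag:
                flags[(a, b)] = flag
    return FstMatrix(pops, fst, raw, estimator, flags=flags)


def _pair_rng(seed: int, a: str, b: str) -> np.random.Generator:
    key = "|".join(sorted((a, b)))
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(key.encode())])
    )


def fst_permutation_test(
    aln: Alignment,
    partition,
    n_permutations: int = 110,
    seed: int = 0,
    estimator: str = "nei_ratio",
) -> FstMatrix:
    """Pairwise Fst with permutation p-values.

    For each population pair, individuals are reassigned between the two
    groups with sizes preserved and Fst recomputed.  The test is exact
    (full enumeration of distinct assignments) whenever that enumeration
    fits in the permutation budget, Monte-Carlo with add-one correction
    otherwise.  Deterministic given ``seed``; p-values do not depend on
    population label order.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    if n_permutations <= 200:
        logger.info(
            "permutation granularity is about %.3f with %d permutations",
            1.0 / (n_permutations + 1), n_permutations,
        )
    point = pairwise_fst(aln, partition, estimator)
    pops = point.populations
    ids, d = raw_difference_matrix(aln, list(partition.members()))
    idx = _group_indices(partition, ids)
    k = len(pops)
    p = np.ones((k, k))
    for i, a in enumerate(pops):
        for j in range(i + 1, k):
            b = pops[j]
            obs = point.fst[i, j]
            # canonical pool order and split size, so p-values are
            # independent of population label order
            a_key, b_key = sorted((a, b))
            first = idx[a] if a == a_key else idx[b]
            pool = np.sort(np.concatenate([idx[a], idx[b]]))
            n1 = len(first)
            n_splits = comb(len(pool), n1)
            if n_splits <= n_permutations:
                hits = total = 0
                for combo in itertools.combinations(range(len(pool)), n1):
                    sel = np.zeros(len(pool), dtype=bool)
                    sel[list(combo)] = True
                    f, _, _ = fst_from_distances(d, pool[sel], pool[~sel], estimator)
                    total += 1
                    if f >= obs - _TIE_EPS:
                        hits += 1
                p[i, j] = p[j, i] = hits / total
            else:
                rng = _pair_rng(seed, a, b)
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(pool)
                    f, _, _ = fst_from_distances(d, perm[:n1], perm[n1:], estimator)
                    if f >= obs - _TIE_EPS:
                        hits += 1
                p[i, j] = p[j, i] = (1 + hits) / (n_permutations + 1)
    return FstMatrix(
        pops, point.fst, point.fst_raw, estimator,
        p_values=p, n_permutations=n_permutations, flags=point.flags,
    )
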