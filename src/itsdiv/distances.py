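"""Pairwise evolutionary distances and Nei population distance tables.

Kimura two-parameter (K2P) distances use pairwise deletion: for each
sequence pair independently, columns where either member carries a gap or
``N`` are excluded, matching the distance-matrix convention of the
standard phylogenetics packages.  Nei within/between/net population
distances are built on *raw difference counts* instead, where a base
opposite a gap is one difference — the convention the haplotype-level
summaries use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .errors import NoOverlapError, ParameterError
from .seq_io import Alignment
from .site_stats import raw_difference_matrix


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled rows/columns."""

    ids: tuple[str, ...]
    data: np.ndarray
    metric: str = "k2p"
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ParameterError("distance matrix shape does not match ids")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.ids)})

    def pair(self, a: str, b: str) -> float:
        return float(self.data[self._index[a], self._index[b]])

    @property
    def has_saturated(self) -> bool:
        return bool(np.isinf(self.data).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))

    def to_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM

        return SkbioDM(self.data, ids=list(self.ids))


def _pair_arr(s1: str, s2: str) -> np.ndarray:
    return Alignment(("s1", "s2"), (s1, s2)).to_array()


def k2p_distance(s1: str, s2: str) -> float:
    """K2P distance between two equal-length gapped sequences.

    Returns ``inf`` when the model saturates (a log argument <= 0).
    Raises :class:`NoOverlapError` if no column is comparable after
    pairwise deletion.
    """
    d = _kernels.k2p_matrix(_pair_arr(s1, s2))[0, 1]
    if math.isnan(d):
        raise NoOverlapError("no comparable columns after pairwise deletion")
    return float(d)


def p_distance(s1: str, s2: str) -> float:
    """Proportion of differing columns among comparable columns."""
    p, comparable = _kernels.p_distance_matrix(_pair_arr(s1, s2))
    if comparable[0, 1] == 0:
        raise NoOverlapError("no comparable columns after pairwise deletion")
    return float(p[0, 1])


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs K2P distances. Saturated pairs are +inf entries."""
    if len(aln) < 2:
        raise ParameterError("k2p_matrix needs at least 2 sequences")
    d = _kernels.k2p_matrix(aln.to_array())
    if np.isnan(d).any():
        i, j = map(int, np.argwhere(np.isnan(d))[0])
        raise NoOverlapError(
            f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    return DistanceMatrix(aln.ids, d, metric="k2p")


def percent_similarity_matrix(aln: Alignment) -> pd.DataFrame:
    """100 * (1 - p-distance) with pairwise deletion, as a DataFrame."""
    p, comparable = _kernels.p_distance_matrix(aln.to_array())
    off_diag = ~np.eye(len(aln), dtype=bool)
    if (comparable[off_diag] == 0).any():
        bad = np.argwhere((comparable == 0) & off_diag)[0]
        raise NoOverlapError(
            f"no comparable columns between {aln.ids[int(bad[0])]!r} and "
            f"{aln.ids[int(bad[1])]!r}"
        )
    return pd.DataFrame(100.0 * (1.0 - p), index=list(aln.ids), columns=list(aln.ids))


@dataclass(frozen=True)
class PopulationDistanceTable:
    """Nei average pairwise differences within/between populations and the
    net between-population distance dA = between - (within_a + within_b)/2.

    ``singletons`` flags populations of one isolate, whose within-distance
    is reported as 0 by convention.
    """

    populations: tuple[str, ...]
    within: dict[str, float]
    between: dict[tuple[str, str], float]
    net: dict[tuple[str, str], float]
    singletons: frozenset[str]

    def _get(self, table: dict, a: str, b: str) -> float:
        return table[(a, b)] if (a, b) in table else table[(b, a)]

    def get_between(self, a: str, b: str) -> float:
        return 0.0 if a == b else self._get(self.between, a, b)

    def get_net(self, a: str, b: str) -> float:
        return 0.0 if a == b else self._get(self.net, a, b)

    def to_dataframe(self) -> pd.DataFrame:
        """Square layout: between above the diagonal, within on it, net below."""
        pops = list(self.populations)
        m = np.zeros((len(pops), len(pops)))
        for i, a in enumerate(pops):
            m[i, i] = self.within[a]
            for j in range(i + 1, len(pops)):
                b = pops[j]
                m[i, j] = self.get_between(a, b)
                m[j, i] = self.get_net(a, b)
        return pd.DataFrame(m, index=pops, columns=pops)


def population_distances(aln: Alignment, partition) -> PopulationDistanceTable:
    """Nei within/between/net distances from raw pairwise difference counts."""
    pops = tuple(partition.groups)
    all_ids = [i for ids in partition.groups.values() for i in ids]
    ids, d = raw_difference_matrix(aln, all_ids)
    pos = {s: k for k, s in enumerate(ids)}
    idx = {p: np.array([pos[i] for i in partition.groups[p]]) for p in pops}

    within: dict[str, float] = {}
    singles = set()
    for p in pops:
        ii = idx[p]
        if len(ii) < 2:
            within[p] = 0.0
            singles.add(p)
        else:
            block = d[np.ix_(ii, ii)]
            iu = np.triu_indices(len(ii), k=1)
            within[p] = float(block[iu].mean())

    between: dict[tuple[str, str], float] = {}
    net: dict[tuple[str, str], float] = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            cross = d[np.ix_(idx[a], idx[b])]
            between[(a, b)] = float(cross.mean())
            net[(a, b)] = between[(a, b)] - (within[a] + within[b]) / 2.0
    return PopulationDistanceTable(pops, within, between, net, frozenset(singles))
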