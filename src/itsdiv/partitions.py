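"""OTU clustering, haplotype collapsing and the per-country haplotype table.

OTUs are clusters of sequences linked by percent similarity
(100 * (1 - p-distance) with pairwise deletion).  Single linkage is the
default — two sequences share an OTU iff they are connected by a chain of
pairs at or above the threshold — with complete linkage available.

Haplotypes are defined over substitution-informative columns only:
columns containing a gap or an ``N`` within the analysed subset are
ignored for identity, so indel-only variation never splits a haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ParameterError, ValidationError
from .seq_io import GAP, MISSING, Alignment
from .distances import percent_similarity_matrix


@dataclass(frozen=True)
class Partition:
    """Disjoint assignment of isolate ids to labelled groups."""

    scheme: str  # otu | haplotype | country | user
    groups: dict[str, tuple[str, ...]]
    threshold: float | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            if not members:
                raise ValidationError(f"empty group {label!r}")
            overlap = seen & set(members)
            if overlap:
                raise ValidationError(f"groups overlap on ids: {sorted(overlap)}")
            seen |= set(members)

    @property
    def labels(self) -> dict[str, str]:
        return {m: label for label, members in self.groups.items() for m in members}

    @property
    def sizes(self) -> dict[str, int]:
        return {label: len(m) for label, m in self.groups.items()}

    def members(self) -> tuple[str, ...]:
        return tuple(m for members in self.groups.values() for m in members)


def _label_groups(clusters: list[list[str]], order: dict[str, int], prefix: str) -> dict[str, tuple[str, ...]]:
    """Label clusters by decreasing size, then first-member input order."""
    for c in clusters:
        c.sort(key=order.__getitem__)
    clusters.sort(key=lambda c: (-len(c), order[c[0]]))
    return {f"{prefix}{k + 1}": tuple(c) for k, c in enumerate(clusters)}


def cluster_otus(
    aln: Alignment,
    threshold_percent: float,
    method: str = "single",
) -> Partition:
    """Agglomerative OTU clustering on percent similarity.

    Two sequences join an OTU iff linked (for ``method='single'``, through
    any chain of intermediates) at similarity >= ``threshold_percent``.
    Labels are ``OTU-1, OTU-2, ...`` by decreasing size then first-member
    order.
    """
    if not (0.0 < threshold_percent <= 100.0):
        raise ParameterError("OTU threshold must be in (0, 100]")
    if method not in ("single", "complete"):
        raise ParameterError(f"unknown linkage method {method!r}")
    order = {s: i for i, s in enumerate(aln.ids)}
    if len(aln) == 1:
        return Partition("otu", {"OTU-1": aln.ids}, threshold_percent)
    sim = percent_similarity_matrix(aln).to_numpy()
    dist = 100.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
    Z = scipy_linkage(squareform(dist, checks=False), method=method)
    # merge clusters at linkage distance <= 100 - threshold, i.e. similarity
    # >= threshold; nudge the cut by an epsilon so boundary pairs merge
    cut = (100.0 - threshold_percent) + 1e-9
    flat = fcluster(Z, t=cut, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for sid, c in zip(aln.ids, flat):
        clusters.setdefault(int(c), []).append(sid)
    return Partition("otu", _label_groups(list(clusters.values()), order, "OTU-"),
                     threshold_percent)


def informative_columns(aln: Alignment, ids=None) -> list[int]:
    """0-based columns free of gaps and N within the subset (haplotype
    identity is evaluated on these columns only)."""
    sub = aln if ids is None else aln.subset(ids)
    cols = []
    for col in range(sub.length):
        symbols = {seq[col] for seq in sub.seqs}
        if GAP not in symbols and MISSING not in symbols:
            cols.append(col)
    return cols


def collapse_haplotypes(aln: Alignment, ids=None) -> Partition:
    """Group sequences identical at every substitution-informative column.

    Labels are ``H1, H2, ...`` by decreasing frequency then first
    occurrence; indel and missing-data columns never separate haplotypes.
    """
    sub = aln if ids is None else aln.subset(ids)
    cols = informative_columns(sub)
    order = {s: i for i, s in enumerate(sub.ids)}
    keys: dict[tuple, list[str]] = {}
    for sid, seq in zip(sub.ids, sub.seqs):
        key = tuple(seq[c] for c in cols)
        keys.setdefault(key, []).append(sid)
    return Partition("haplotype", _label_groups(list(keys.values()), order, "H"))


def country_haplotype_table(
    aln: Alignment,
    samples: pd.DataFrame,
    min_isolates: int = 4,
    subsample_to: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, Partition]:
    """Haplotype counts and relative frequencies per country.

    Countries with fewer than ``min_isolates`` isolates are excluded; each
    retained country is subsampled without replacement (seeded) to
    ``subsample_to`` isolates, haplotypes are collapsed over the pooled
    subsample, and per-country counts plus relative frequencies reported.

    Returns a tidy frame (haplotype, representative, country, count,
    rel_freq) and the pooled haplotype partition.
    """
    if min_isolates < 2:
        raise ParameterError("min_isolates must be >= 2")
    rng = np.random.default_rng(seed)
    counts = samples["country"].value_counts()
    # iterate countries in first-appearance order for determinism
    countries = [c for c in dict.fromkeys(samples["country"]) if counts[c] >= min_isolates]
    pooled: list[str] = []
    chosen: dict[str, list[str]] = {}
    for country in countries:
        ids = [s for s in samples.index if samples.at[s, "country"] == country]
        if len(ids) > subsample_to:
            pick = rng.choice(len(ids), size=subsample_to, replace=False)
            ids = [ids[k] for k in sorted(pick)]
        chosen[country] = ids
        pooled.extend(ids)
    if not pooled:
        empty = pd.DataFrame(
            columns=["haplotype", "representative", "country", "count", "rel_freq"]
        )
        return empty, None
    haps = collapse_haplotypes(aln, pooled)
    labels = haps.labels
    rows = []
    for hap, members in haps.groups.items():
        rep = members[0]
        for country in countries:
            n_members = sum(1 for s in chosen[country] if labels[s] == hap)
            rows.append({
                "haplotype": hap,
                "representative": rep,
                "country": country,
                "count": n_members,
                "rel_freq": n_members / len(chosen[country]),
            })
    return pd.DataFrame(rows), haps
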