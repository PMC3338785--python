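"""Per-column variation classes and per-population summary statistics.

Each alignment column is classified as monomorphic, transition,
transversion, mixed substitution (three or more base alleles), indel, or
indel-plus-substitution.  *Site* counts tally columns per category; *event*
counts tally, per column, the number of distinct alleles minus one, so the
two agree exactly on strictly biallelic data.

The mean number of pairwise differences counts base-vs-base and
base-vs-gap mismatches alike (one per column), with columns where either
member of a pair carries ``N`` excluded for that pair.  This is the
convention under which a population whose only variation is a single indel
column shared by half its members has a nonzero mean pairwise difference
even though it contains a single haplotype.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ComputationError, InsufficientSampleError
from .seq_io import GAP, MISSING, Alignment

MONOMORPHIC = "monomorphic"
TRANSITION = "transition"
TRANSVERSION = "transversion"
MIXED_SUBSTITUTION = "mixed_substitution"
INDEL = "indel"
INDEL_PLUS_SUBSTITUTION = "indel_plus_substitution"

BASES = ("A", "C", "G", "T")
TS_PAIRS = frozenset({frozenset("AG"), frozenset("CT")})


@dataclass(frozen=True)
class SiteClass:
    """Classification of one alignment column (1-based ``column``)."""

    column: int
    kind: str
    alleles: tuple[tuple[str, int], ...]  # (symbol, count), sorted by symbol

    @property
    def base_alleles(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.alleles if s in BASES)

    @property
    def has_gap(self) -> bool:
        return any(s == GAP for s, _ in self.alleles)


@dataclass(frozen=True)
class SiteCounts:
    transition_sites: int
    transversion_sites: int
    substitution_sites: int
    indel_sites: int

    @property
    def polymorphic_sites(self) -> int:
        # A column that is both indel and substitution increments both
        # categories; this is reported, not hidden.
        return self.substitution_sites + self.indel_sites


@dataclass(frozen=True)
class EventCounts:
    transitions: int
    transversions: int
    substitutions: int
    indels: int


def classify_sites(aln: Alignment, ids=None) -> list[SiteClass]:
    """Classify every column of the alignment (or of a subset of rows)."""
    sub = aln if ids is None else aln.subset(ids)
    result = []
    for col in range(sub.length):
        counts = Counter(seq[col] for seq in sub.seqs)
        counts.pop(MISSING, None)  # N is missing data, never an allele
        bases = {s for s in counts if s in BASES}
        has_gap = GAP in counts and bases
        if has_gap:
            kind = INDEL if len(bases) == 1 else INDEL_PLUS_SUBSTITUTION
        elif len(bases) >= 3:
            kind = MIXED_SUBSTITUTION
        elif len(bases) == 2:
            kind = TRANSITION if frozenset(bases) in TS_PAIRS else TRANSVERSION
        else:
            kind = MONOMORPHIC
        alleles = tuple(sorted(counts.items()))
        result.append(SiteClass(column=col + 1, kind=kind, alleles=alleles))
    return result


def count_sites(sites: list[SiteClass]) -> SiteCounts:
    ts = tv = sub = ind = 0
    for s in sites:
        bases = s.base_alleles
        if len(bases) >= 2:
            sub += 1
            if len(bases) == 2:
                if frozenset(bases) in TS_PAIRS:
                    ts += 1
                else:
                    tv += 1
        if s.has_gap and bases:
            ind += 1
    return SiteCounts(ts, tv, sub, ind)


def count_events(sites: list[SiteClass]) -> EventCounts:
    """Events per category: distinct alleles at a column minus one.

    Columns with three or more base alleles contribute to the substitution
    total but are not split into transitions/transversions.
    """
    ts = tv = sub = ind = 0
    for s in sites:
        bases = s.base_alleles
        if len(bases) >= 2:
            sub += len(bases) - 1
            if len(bases) == 2:
                if frozenset(bases) in TS_PAIRS:
                    ts += 1
                else:
                    tv += 1
        if s.has_gap and bases:
            ind += 1
    return EventCounts(ts, tv, sub, ind)


def raw_difference_matrix(aln: Alignment, ids=None) -> tuple[tuple[str, ...], np.ndarray]:
    """All-pairs counts of differing columns (indels count, N excluded)."""
    sub = aln if ids is None else aln.subset(ids)
    return sub.ids, _kernels.raw_difference_matrix(sub.to_array())


def mean_pairwise_differences(aln: Alignment, ids=None) -> float:
    """Mean difference count over all unordered sequence pairs."""
    sub = aln if ids is None else aln.subset(ids)
    n = len(sub)
    if n < 2:
        raise InsufficientSampleError(
            f"mean pairwise differences needs >= 2 sequences, got {n}"
        )
    _, d = raw_difference_matrix(sub)
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def nucleotide_composition(aln: Alignment, ids=None) -> dict[str, float]:
    """Pooled A/C/G/T percentages; gaps and N excluded from the denominator."""
    sub = aln if ids is None else aln.subset(ids)
    counts = Counter(itertools.chain.from_iterable(sub.seqs))
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise ComputationError("composition undefined: no unambiguous bases")
    return {b: 100.0 * counts[b] / total for b in BASES}


SUMMARY_COLUMNS = [
    "population", "n",
    "pct_C", "pct_T", "pct_A", "pct_G",
    "n_transitions", "n_transversions", "n_substitutions", "n_indels",
    "n_polymorphic_sites",
    "n_transition_sites", "n_transversion_sites", "n_substitution_sites",
    "n_indel_sites",
    "mean_pairwise_differences", "theta_S", "theta_pi",
    "n_haplotypes", "haplotype_frequencies",
]


def summarize_populations(aln: Alignment, partition) -> pd.DataFrame:
    """One summary row per population: composition, site and event counts,
    mean pairwise differences, theta estimators and haplotype structure.

    Populations of a single isolate get zero diversity values by
    convention (no pair exists to compare).
    """
    from .diversity import theta_estimates
    from .partitions import collapse_haplotypes

    rows = []
    for label, ids in partition.groups.items():
        ids = list(ids)
        comp = nucleotide_composition(aln, ids)
        sites = classify_sites(aln, ids)
        sc = count_sites(sites)
        ev = count_events(sites)
        if len(ids) >= 2:
            theta = theta_estimates(aln, ids)
            pi = theta.theta_pi
            theta_s = theta.theta_S
        else:
            pi = theta_s = 0.0
        haps = collapse_haplotypes(aln, ids)
        freqs = sorted((len(m) for m in haps.groups.values()), reverse=True)
        rows.append({
            "population": label,
            "n": len(ids),
            "pct_C": comp["C"], "pct_T": comp["T"],
            "pct_A": comp["A"], "pct_G": comp["G"],
            "n_transitions": ev.transitions,
            "n_transversions": ev.transversions,
            "n_substitutions": ev.substitutions,
            "n_indels": ev.indels,
            "n_polymorphic_sites": sc.polymorphic_sites,
            "n_transition_sites": sc.transition_sites,
            "n_transversion_sites": sc.transversion_sites,
            "n_substitution_sites": sc.substitution_sites,
            "n_indel_sites": sc.indel_sites,
            "mean_pairwise_differences": pi,
            "theta_S": theta_s,
            "theta_pi": pi,
            "n_haplotypes": len(haps.groups),
            "haplotype_frequencies": ",".join(str(f) for f in freqs),
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
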