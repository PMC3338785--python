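"""Synthetic alignments with prescribed haplotype structure.

The generator builds conspecific barcode-style alignments in which every
downstream statistic has a closed-form expected value: a random reference
sequence, one scaffold per population differing from the reference at a
fixed number of private columns, and at most two sequence variants per
population separated by a stated number of transition, transversion and
single-column indel sites.  All mutated columns are pairwise distinct, so
within-population divergence, between-population divergence and the
site-category counts are exactly the specified ones.

Because the expected statistics depend only on this difference structure
(never on the random base content), two seeds give different sequences
but identical expected summaries — which is what makes the generator a
usable ground truth for the whole pipeline.

``table1_preset`` reproduces the nine-population structure observed in
the study this package reimplements: population sizes
(16, 2, 12, 3, 8, 3, 8, 3, 8), two of the diverse populations split
2/1 and 6/2 over haplotypes differing at 2 transition + 5 transversion +
1 indel columns, and one population whose only variation is a single
indel column carried by 4 of its 8 members (the split that yields a mean
pairwise difference of 16/28 = 0.57).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .diversity import harmonic_number
from .errors import ParameterError
from .partitions import Partition
from .seq_io import Alignment

_GAP_CODE = 4

COUNTRIES = ("Portugal", "Spain", "Czech Republic", "Malaysia",
             "Japan", "Canada", "Germany", "United Kingdom")
SUBSTRATES = ("leaves", "twigs", "foam", "stream water")


@dataclass(frozen=True)
class PopulationSpec:
    """Difference structure of one population.

    ``haplotype_counts`` are the copy numbers of the (at most two)
    sequence variants, non-increasing; ``diffs_between_haplotypes`` gives
    the transition, transversion and single-column indel sites separating
    variant 2 from variant 1; ``scaffold_divergence`` is the number of
    private columns at which this population's scaffold differs from the
    shared reference.
    """

    label: str
    n: int
    haplotype_counts: tuple[int, ...] = None
    diffs_between_haplotypes: tuple[int, int, int] = (0, 0, 0)
    scaffold_divergence: int = 12

    def __post_init__(self) -> None:
        hc = self.haplotype_counts
        if hc is None:
            hc = (self.n,)
        hc = tuple(int(c) for c in hc)
        object.__setattr__(self, "haplotype_counts", hc)
        if len(hc) > 2:
            raise ParameterError(
                f"{self.label}: more than 2 haplotypes per population is "
                "outside the generated regime"
            )
        if sum(hc) != self.n:
            raise ParameterError(f"{self.label}: haplotype counts must sum to n")
        if any(c <= 0 for c in hc):
            raise ParameterError(f"{self.label}: haplotype counts must be positive")
        if list(hc) != sorted(hc, reverse=True):
            raise ParameterError(f"{self.label}: haplotype counts must be non-increasing")
        if any(x < 0 for x in self.diffs_between_haplotypes) or self.scaffold_divergence < 0:
            raise ParameterError(f"{self.label}: negative difference counts")
        if len(hc) == 1 and sum(self.diffs_between_haplotypes) > 0:
            raise ParameterError(
                f"{self.label}: haplotype differences given for a single-variant population"
            )

    @property
    def n_diff_columns(self) -> int:
        return sum(self.diffs_between_haplotypes)

    def columns_needed(self) -> int:
        return self.scaffold_divergence + self.n_diff_columns


@dataclass(frozen=True)
class DatasetSpec:
    """Full synthetic-dataset specification."""

    population_specs: tuple[PopulationSpec, ...]
    alignment_length: int = 464
    min_scaffold_separation: int = 12
    seed: int = 20120427

    def __post_init__(self) -> None:
        object.__setattr__(self, "population_specs", tuple(self.population_specs))
        if not self.population_specs:
            raise ParameterError("at least one population is required")
        total = sum(p.columns_needed() for p in self.population_specs)
        if total > self.alignment_length:
            raise ParameterError(
                f"column budget exceeded: {total} mutated columns in a "
                f"{self.alignment_length}-column alignment"
            )
        specs = self.population_specs
        for i, a in enumerate(specs):
            for b in specs[i + 1:]:
                sep = a.scaffold_divergence + b.scaffold_divergence
                if len(specs) > 1 and sep < self.min_scaffold_separation:
                    raise ParameterError(
                        f"scaffolds {a.label}/{b.label} separated by {sep} "
                        f"columns < min_scaffold_separation="
                        f"{self.min_scaffold_separation}"
                    )


def expected_population_summary(spec: PopulationSpec) -> dict:
    """Closed-form expected diversity statistics for one population.

    Derivable directly from the difference structure: with two variants of
    copy numbers (c1, c2) separated by D columns, the mean pairwise
    difference is D * c1 * c2 / C(n, 2); S = D; theta_S = S / a_n.  The
    haplotype count ignores indel-only variation.
    """
    ts, tv, ind = spec.diffs_between_haplotypes
    n = spec.n
    hc = spec.haplotype_counts
    D = spec.n_diff_columns
    if len(hc) == 2 and D > 0:
        pi = D * hc[0] * hc[1] / comb(n, 2)
    else:
        pi = 0.0
    n_hap = 2 if (len(hc) == 2 and ts + tv > 0) else 1
    hap_freqs = list(hc) if n_hap == 2 else [n]
    a_n = harmonic_number(n - 1)
    return {
        "population": spec.label,
        "n": n,
        "n_transitions": ts, "n_transversions": tv,
        "n_substitutions": ts + tv, "n_indels": ind,
        "n_polymorphic_sites": D,
        "n_transition_sites": ts, "n_transversion_sites": tv,
        "n_substitution_sites": ts + tv, "n_indel_sites": ind,
        "mean_pairwise_differences": pi,
        "theta_S": (D / a_n) if a_n > 0 else 0.0,
        "theta_pi": pi,
        "n_haplotypes": n_hap,
        "haplotype_frequencies": ",".join(str(f) for f in sorted(hap_freqs, reverse=True)),
    }


_TV_PARTNERS = {0: (1, 3), 2: (1, 3), 1: (0, 2), 3: (0, 2)}  # purine<->pyrimidine


def generate_dataset(spec: DatasetSpec):
    """Generate (alignment, sample table, truth).

    ``truth`` is a dict with the ground-truth ``partition`` (one group per
    population) and ``expected``, the list of closed-form per-population
    summaries from :func:`expected_population_summary`.  Fully
    deterministic given ``spec.seed``; country/substrate/date metadata are
    decorative draws that no statistic depends on.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.alignment_length
    total_cols = sum(p.columns_needed() for p in spec.population_specs)
    mutated = rng.choice(L, size=total_cols, replace=False)
    ref = rng.integers(0, 4, size=L, dtype=np.int64)

    ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: list[dict] = []
    groups: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for pop in spec.population_specs:
        cols = mutated[cursor:cursor + pop.columns_needed()]
        cursor += pop.columns_needed()
        scaffold_cols = cols[:pop.scaffold_divergence]
        hap_cols = cols[pop.scaffold_divergence:]

        scaffold = ref.copy()
        for c in scaffold_cols:
            scaffold[c] = (scaffold[c] + rng.integers(1, 4)) % 4

        variants = [scaffold]
        if len(pop.haplotype_counts) == 2:
            ts, tv, ind = pop.diffs_between_haplotypes
            v2 = scaffold.copy()
            ts_cols = hap_cols[:ts]
            tv_cols = hap_cols[ts:ts + tv]
            ind_cols = hap_cols[ts + tv:]
            for c in ts_cols:
                v2[c] = scaffold[c] ^ 2  # A<->G, C<->T under the 0..3 coding
            for c in tv_cols:
                v2[c] = _TV_PARTNERS[int(scaffold[c])][rng.integers(0, 2)]
            for c in ind_cols:
                v2[c] = _GAP_CODE
            variants.append(v2)

        members = []
        k = 0
        for variant, copies in zip(variants, pop.haplotype_counts):
            for _ in range(copies):
                k += 1
                sid = f"{pop.label}-{k:02d}"
                ids.append(sid)
                rows.append(variant)
                members.append(sid)
                meta.append({
                    "isolate_id": sid,
                    "population": pop.label,
                    "country": COUNTRIES[rng.integers(0, len(COUNTRIES))],
                    "substrate": SUBSTRATES[rng.integers(0, len(SUBSTRATES))],
                    "date": f"{2000 + rng.integers(0, 11)}-{rng.integers(1, 13):02d}-{rng.integers(1, 29):02d}",
                })
        groups[pop.label] = tuple(members)

    aln = Alignment.from_array(ids, np.vstack(rows))
    samples = pd.DataFrame(meta).set_index("isolate_id")
    truth = {
        "partition": Partition("otu", groups),
        "expected": [expected_population_summary(p) for p in spec.population_specs],
    }
    return aln, samples, truth


def table1_preset(seed: int = 20120427, alignment_length: int = 464,
                  scaffold_divergence: int = 12) -> DatasetSpec:
    """Nine populations with the observed barcode haplotype structure.

    The default between-scaffold divergence of 12 columns per population
    (about 2.6% of a 464-column alignment) keeps within-population
    divergence (at most 8 columns) strictly below between-population
    divergence, echoing the conspecific regime of at most ~1.3% within
    versus ~2.2% maximum overall.
    """
    def ps(label, n, hc=None, diffs=(0, 0, 0)):
        return PopulationSpec(label, n, hc, diffs, scaffold_divergence)

    return DatasetSpec(
        population_specs=(
            ps("OTU-1", 16),
            ps("OTU-2", 2),
            ps("OTU-3", 12),
            ps("OTU-4", 3),
            ps("OTU-5", 8),
            ps("OTU-6", 3),
            ps("OTU-7", 8, (4, 4), (0, 0, 1)),
            ps("OTU-8", 3, (2, 1), (2, 5, 1)),
            ps("OTU-9", 8, (6, 2), (2, 5, 1)),
        ),
        alignment_length=alignment_length,
        seed=seed,
    )


def neutral_panmictic_preset(
    n: int,
    mu_columns: int,
    replicates: int,
    seed: int = 0,
    alignment_length: int = 464,
) -> list[Alignment]:
    """Unstructured replicate alignments for estimator-agreement checks.

    Each replicate carries exactly ``mu_columns`` biallelic substitution
    columns.  The number of sequences carrying the derived base at a
    column is drawn from the neutral infinite-sites frequency spectrum
    (P(k) proportional to 1/k, k = 1..n-1), under which the Watterson and
    pairwise-difference estimators have identical expectation, and the
    carriers are a uniform subset of that size.
    """
    if n < 4:
        raise ParameterError("neutral preset needs n >= 4")
    if mu_columns > alignment_length:
        raise ParameterError("more mutated columns than alignment columns")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, n)
    weights = (1.0 / ks) / (1.0 / ks).sum()
    out = []
    for r in range(replicates):
        ref = rng.integers(0, 4, size=alignment_length, dtype=np.int64)
        arr = np.tile(ref, (n, 1))
        cols = rng.choice(alignment_length, size=mu_columns, replace=False)
        for c in cols:
            k = int(rng.choice(ks, p=weights))
            carriers = rng.choice(n, size=k, replace=False)
            arr[carriers, c] = (ref[c] + rng.integers(1, 4)) % 4
        ids = [f"rep{r:03d}-s{i:02d}" for i in range(n)]
        out.append(Alignment.from_array(ids, arr))
    return out
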