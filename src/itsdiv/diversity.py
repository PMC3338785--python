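"""Molecular-diversity estimators theta_S and theta_pi.

Both estimators are reported *per locus* (raw difference-count units, not
per site), matching how mean pairwise differences are tabulated for short
barcode loci.  ``theta_S`` is the Watterson estimator S / a_n with
a_n = sum_{i=1}^{n-1} 1/i; ``theta_pi`` is the mean number of pairwise
differences.  The segregating-site count S includes single-column indel
sites, consistently with the pairwise-difference convention (a base
opposite a gap is one difference).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InsufficientSampleError
from .seq_io import Alignment
from .site_stats import classify_sites, count_sites, mean_pairwise_differences


def harmonic_number(n_minus_1: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (0 for n = 1)."""
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


@dataclass(frozen=True)
class ThetaEstimates:
    population: str
    n: int
    S: int
    a_n: float
    theta_S: float
    theta_pi: float


def theta_estimates(aln: Alignment, ids=None, population: str = "") -> ThetaEstimates:
    """Watterson and pairwise-difference theta for one population."""
    sub = aln if ids is None else aln.subset(ids)
    n = len(sub)
    if n < 2:
        raise InsufficientSampleError(f"theta estimators need >= 2 sequences, got {n}")
    sc = count_sites(classify_sites(sub))
    S = sc.polymorphic_sites
    a_n = harmonic_number(n - 1)
    return ThetaEstimates(
        population=population,
        n=n,
        S=S,
        a_n=a_n,
        theta_S=S / a_n,
        theta_pi=mean_pairwise_differences(sub),
    )
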