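import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from itsdiv import generate_dataset, table1_preset
from itsdiv.seq_io import Alignment

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def aln_from(seqs, ids=None) -> Alignment:
    """Build an alignment from raw sequence strings."""
    seqs = tuple(s.upper() for s in seqs)
    if ids is None:
        ids = tuple(f"s{i}" for i in range(len(seqs)))
    return Alignment(tuple(ids), seqs)


def two_haplotype_alignment(counts, n_ts=0, n_tv=0, n_indel=0, length=60, seed=0):
    """Two sequence variants at given copy numbers, separated by the stated
    transition / transversion / single-column indel sites.

    Written independently of the package's generator: explicit base edits
    on a literal reference.
    """
    rng = np.random.default_rng(seed)
    ref = rng.choice(list("ACGT"), size=length).tolist()
    total = n_ts + n_tv + n_indel
    cols = rng.choice(length, size=total, replace=False)
    ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_partner = {"A": "C", "G": "T", "C": "A", "T": "G"}
    v2 = ref.copy()
    for c in cols[:n_ts]:
        v2[c] = ts_partner[ref[c]]
    for c in cols[n_ts:n_ts + n_tv]:
        v2[c] = tv_partner[ref[c]]
    for c in cols[n_ts + n_tv:]:
        v2[c] = "-"
    seqs = ["".join(ref)] * counts[0] + ["".join(v2)] * (counts[1] if len(counts) > 1 else 0)
    return aln_from(seqs)


@pytest.fixture(scope="session")
def table1():
    """(alignment, samples, truth, spec) for the nine-population preset."""
    spec = table1_preset()
    aln, samples, truth = generate_dataset(spec)
    return aln, samples, truth, spec
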