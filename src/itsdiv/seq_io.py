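"""Reading and validating aligned FASTA and sample metadata; Newick I/O.

The :class:`Alignment` is the single substrate every statistic in the
package is computed on: an ordered set of equal-length gapped sequences
over the alphabet ``{A, C, G, T, N, -}``.  ``N`` is missing data and is
excluded from every pairwise comparison; ``-`` is the only accepted gap
character (``.`` is rejected rather than guessed at).

Columns are indexed 0-based internally; every user-facing report uses
1-based column numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .errors import AlignmentError, CrossReferenceError, ValidationError

GAP = "-"
MISSING = "N"
ALPHABET = frozenset("ACGTN-")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, GAP: 4, MISSING: 5}
_DECODE = np.frombuffer(b"ACGT-N", dtype=np.uint8)

_ENCODE_TABLE = np.full(128, 255, dtype=np.uint8)
for _sym, _code in _CODE.items():
    _ENCODE_TABLE[ord(_sym)] = _code

SAMPLE_COLUMNS = ("isolate_id", "population", "country", "substrate", "date")


@dataclass(frozen=True)
class Alignment:
    """An immutable multiple sequence alignment.

    Parameters
    ----------
    ids : tuple of str
        Unique, non-empty sequence identifiers, in input order.
    seqs : tuple of str
        Upper-case gapped sequences of identical length over ``ACGTN-``.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if not self.ids:
            raise AlignmentError("alignment is empty")
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError(f"zero-length sequence for id {self.ids[0]!r}")
        for sid, seq in zip(self.ids, self.seqs):
            if not sid:
                raise AlignmentError("empty sequence id")
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid symbols: "
                    f"{''.join(sorted(bad))}"
                )
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dups: set[str] = set()
            for sid in self.ids:
                if sid in seen:
                    dups.add(sid)
                seen.add(sid)
            raise AlignmentError(f"duplicate sequence ids: {sorted(dups)}")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.ids)})

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, sid: str) -> str:
        return self.seqs[self._index[sid]]

    def subset(self, ids) -> "Alignment":
        """Alignment restricted to ``ids``, in the order given."""
        ids = tuple(ids)
        missing = [s for s in ids if s not in self._index]
        if missing:
            raise CrossReferenceError(f"ids not in alignment: {missing}")
        return Alignment(ids, tuple(self.seqs[self._index[s]] for s in ids))

    def to_array(self) -> np.ndarray:
        """Integer-coded matrix (n, length), dtype uint8 (see _kernels)."""
        raw = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8)
        return _ENCODE_TABLE[raw].reshape(len(self.ids), self.length)

    @classmethod
    def from_array(cls, ids, arr: np.ndarray) -> "Alignment":
        seqs = tuple(bytes(_DECODE[row]).decode() for row in np.asarray(arr, dtype=np.intp))
        return cls(tuple(ids), seqs)

    def drop_all_gap_columns(self) -> "Alignment":
        arr = self.to_array()
        keep = ~(arr == _CODE[GAP]).all(axis=0)
        if keep.all():
            return self
        if not keep.any():
            raise AlignmentError("alignment consists only of gap columns")
        return Alignment.from_array(self.ids, arr[:, keep])


def read_alignment(path, strip_all_gap_columns: bool = True) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased and ``U`` is mapped to ``T``.  Columns that
    are gaps in every sequence (alignment-deposit padding) are stripped by
    default; pass ``strip_all_gap_columns=False`` to retain them.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper().replace("U", "T") for r in records)
    length = len(seqs[0])
    for sid, seq in zip(ids, seqs):
        if len(seq) != length:
            raise AlignmentError(
                f"ragged alignment in {path}: sequence {sid!r} has length "
                f"{len(seq)}, expected {length}"
            )
    aln = Alignment(ids, seqs)
    if strip_all_gap_columns:
        aln = aln.drop_all_gap_columns()
    return aln


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def _normalize_date(value: str) -> str:
    value = value.strip()
    if not value:
        return ""
    ts = pd.to_datetime(value, errors="coerce")
    if pd.isna(ts):
        return ""
    return ts.date().isoformat()


def read_samples(path, aln: Alignment) -> pd.DataFrame:
    """Read the isolate metadata TSV and cross-check it against ``aln``.

    Returns a DataFrame indexed by ``isolate_id`` with columns
    ``population``, ``country``, ``substrate`` and ``date`` (ISO-8601 or
    empty).  Dates are tolerated in free text on input and never used in
    any computation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"sample table missing columns: {missing_cols}")
    dup = df["isolate_id"][df["isolate_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicated isolate_id rows: {sorted(set(dup))}")
    unknown = [s for s in df["isolate_id"] if s not in set(aln.ids)]
    if unknown:
        raise CrossReferenceError(
            f"isolates in sample table absent from alignment: {unknown}"
        )
    empty_pop = df.loc[df["population"].str.strip() == "", "isolate_id"].tolist()
    if empty_pop:
        raise ValidationError(f"empty population label for isolates: {empty_pop}")
    df = df.set_index("isolate_id")
    df["date"] = [_normalize_date(v) for v in df["date"]]
    return df[["population", "country", "substrate", "date"]]


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree as Newick with branch lengths and any internal-node
    support values (stored as internal node names)."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_table(df: pd.DataFrame, path, float_format: str = "%.4f", index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format, lineterminator="\n")
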