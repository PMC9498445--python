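"""Sequence records, interaction matrices and dataset assembly.

A dataset couples two entity sets -- miRNAs (~22 nt regulatory RNAs) and
mRNA target sites (short subsequences, typically 30-40 nt, where a miRNA
may bind) -- with a binary adjacency matrix of experimentally supported
interactions.  Listed pairs are the positive class; every other cell of
the matrix is treated as negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Role",
    "SequenceRecord",
    "InteractionMatrix",
    "Dataset",
    "read_fasta",
    "filter_records",
    "trim_site",
    "read_interactions",
    "sample_submatrix",
]

_ALPHABET = set("ACGUN")


class FileFormatError(ValueError):
    """Raised when an input file violates the expected format."""


class Role(str, enum.Enum):
    MIRNA = "miRNA"
    TARGET_SITE = "target_site"


@dataclass(frozen=True)
class SequenceRecord:
    """One miRNA or target-site sequence.

    The sequence is stored uppercase over the RNA alphabet {A,C,G,U,N};
    DNA input is accepted upstream and T is mapped to U.
    """

    id: str
    role: Role
    sequence: str
    source_transcript: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid letters {sorted(bad)} "
                "(allowed: A, C, G, U, N and T on input)"
            )


@dataclass
class InteractionMatrix:
    """Binary adjacency A over ordered miRNA rows and target-site columns."""

    mirna_ids: list[str]
    site_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.mirna_ids), len(self.site_ids)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match id lists "
                f"({len(self.mirna_ids)} x {len(self.site_ids)})"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids in interaction matrix")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids in interaction matrix")
        vals = np.unique(self.A)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.A = self.A.astype(np.int8)

    @property
    def n_m(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_t(self) -> int:
        return len(self.site_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.A, index=self.mirna_ids, columns=self.site_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


@dataclass
class Dataset:
    """Sequences plus their interaction matrix; ids must be consistent."""

    mirnas: list[SequenceRecord]
    sites: list[SequenceRecord]
    interactions: InteractionMatrix
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mids = [r.id for r in self.mirnas]
        tids = [r.id for r in self.sites]
        if self.interactions.mirna_ids != mids:
            raise ValueError("interaction miRNA ids do not match miRNA records")
        if self.interactions.site_ids != tids:
            raise ValueError("interaction site ids do not match site records")

    @property
    def mirna_sequences(self) -> list[str]:
        return [r.sequence for r in self.mirnas]

    @property
    def site_sequences(self) -> list[str]:
        return [r.sequence for r in self.sites]


def _normalize_sequence(record_id: str, raw: str) -> str:
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - _ALPHABET
    if bad:
        raise FileFormatError(
            f"record {record_id!r}: invalid letters {sorted(bad)}"
        )
    return seq


def read_fasta(path, role: Role) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into sequence records.

    Sequences are uppercased and T is mapped to U.  Duplicate ids within
    the file and empty sequences raise ``FileFormatError``.
    """
    role = Role(role)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FileFormatError(f"{path}: FASTA entry with empty header")
        if rec.id in seen:
            raise FileFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FileFormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(
            SequenceRecord(id=rec.id, role=role, sequence=_normalize_sequence(rec.id, seq))
        )
    return records


def filter_records(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Apply the N-content filters, preserving input order.

    miRNAs with one or more N letters are removed outright; target sites
    are removed only when more than half of their positions are N.
    """
    kept = []
    for rec in records:
        n_frac = rec.sequence.count("N") / len(rec.sequence)
        if rec.role is Role.MIRNA and n_frac > 0:
            continue
        if rec.role is Role.TARGET_SITE and n_frac > 0.5:
            continue
        kept.append(rec)
    return kept


def trim_site(seq: str, target_length: int) -> str:
    """Return the centered window of ``target_length`` nucleotides.

    Sequences at or below the target length pass through unchanged.  On an
    odd overhang the window sits one position closer to the 5' end.
    """
    if target_length < 1:
        raise ValueError(f"target_length must be >= 1, got {target_length}")
    if len(seq) <= target_length:
        return seq
    start = (len(seq) - target_length) // 2
    return seq[start : start + target_length]


def read_interactions(path, dataset: Dataset | None = None, *,
                      mirna_ids: list[str] | None = None,
                      site_ids: list[str] | None = None) -> InteractionMatrix:
    """Build the binary adjacency matrix from a pair table.

    The TSV must carry a header with columns ``mirna_id`` and ``site_id``
    and optionally ``label`` (0/1; missing label means positive).  Listed
    positive pairs become 1-cells; every other cell is 0.
    """
    if dataset is not None:
        mirna_ids = [r.id for r in dataset.mirnas]
        site_ids = [r.id for r in dataset.sites]
    if mirna_ids is None or site_ids is None:
        raise ValueError("provide either a dataset or explicit id lists")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "site_id"}
    if not required.issubset(df.columns):
        raise FileFormatError(
            f"{path}: interaction table must have columns mirna_id, site_id"
        )
    m_index = {m: i for i, m in enumerate(mirna_ids)}
    t_index = {t: j for j, t in enumerate(site_ids)}
    A = np.zeros((len(mirna_ids), len(site_ids)), dtype=np.int8)
    seen: dict[tuple[str, str], int] = {}
    for row in df.itertuples(index=False):
        m, t = row.mirna_id, row.site_id
        if m not in m_index:
            raise FileFormatError(f"unknown miRNA id {m!r}")
        if t not in t_index:
            raise FileFormatError(f"unknown site id {t!r}")
        label = int(getattr(row, "label", 1) if hasattr(row, "label") else 1)
        if label not in (0, 1):
            raise FileFormatError(f"pair ({m}, {t}): label must be 0 or 1")
        if (m, t) in seen and seen[(m, t)] != label:
            raise FileFormatError(f"pair ({m}, {t}): conflicting duplicate labels")
        seen[(m, t)] = label
        A[m_index[m], t_index[t]] = label
    return InteractionMatrix(list(mirna_ids), list(site_ids), A)


def sample_submatrix(matrix: InteractionMatrix, k: int | None = None,
                     l: int | None = None, seed: int = 0,
                     require_positive_rows: bool = False,
                     max_resample: int = 100) -> InteractionMatrix:
    """Uniformly sample a k x l submatrix of the adjacency matrix.

    Rows and columns are drawn independently without replacement; the
    sampled index order follows the source matrix.  Defaults follow the
    whole-rows / 10%-of-columns scheme used for tractable cross-validation
    (k = n_m, l = round(0.1 * n_t)).  With ``require_positive_rows`` the
    columns are redrawn until every row retains at least one positive.
    """
    if k is None:
        k = matrix.n_m
    if l is None:
        l = max(1, round(0.1 * matrix.n_t))
    if k > matrix.n_m or l > matrix.n_t:
        raise ValueError(
            f"requested {k}x{l} submatrix exceeds matrix dims "
            f"{matrix.n_m}x{matrix.n_t}"
        )
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(matrix.n_m, size=k, replace=False))
    for _ in range(max_resample):
        cols = np.sort(rng.choice(matrix.n_t, size=l, replace=False))
        sub = matrix.A[np.ix_(rows, cols)]
        if not require_positive_rows or (sub.sum(axis=1) > 0).all():
            break
    else:
        raise RuntimeError(
            f"could not find a column sample giving every row a positive "
            f"after {max_resample} draws"
        )
    return InteractionMatrix(
        [matrix.mirna_ids[i] for i in rows],
        [matrix.site_ids[j] for j in cols],
        sub,
    )
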