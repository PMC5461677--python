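"""Aligned-sequence I/O and pairwise divergence matrices.

Sequences are uncorrected percent p-distances with pairwise deletion of
gap ('-') and ambiguous ('N') sites.  Matrices are grouped by an arbitrary
record attribute (host population, morphospecies, genotype) and summarised
with either the maximum or the mean over cross-group pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import AlignmentError, InputError, UndefinedDistanceError

VALID_RESIDUES = frozenset("ACGTN-")

#: alignment symbols excluded from a pairwise comparison
_EXCLUDED = frozenset("-N")


@dataclass(frozen=True)
class SeqRecord:
    """One aligned nucleotide sequence with optional specimen metadata."""

    id: str
    residues: str
    morphospecies: str | None = None
    host_population: str | None = None
    genotype: int | None = None
    locus: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence id must be non-empty")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise AlignmentError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedSeqSet:
    """A set of equal-length sequences at one locus."""

    locus: str
    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"unequal sequence lengths in alignment: {sorted(lengths)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.records)

    def get(self, seq_id: str) -> SeqRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, ids: Iterable[str] | None = None, **attrs) -> "AlignedSeqSet":
        """Records matching all given attribute values (and ids if given)."""
        wanted = set(ids) if ids is not None else None
        out = []
        for r in self.records:
            if wanted is not None and r.id not in wanted:
                continue
            if all(getattr(r, k) == v for k, v in attrs.items()):
                out.append(r)
        if not out:
            raise InputError(f"no records match {attrs!r}")
        return AlignedSeqSet(locus=self.locus, records=out)


def _parse_header(header: str) -> dict:
    """Parse ``id|morphospecies|host|GT`` headers; trailing fields optional."""
    parts = header.split("|")
    meta: dict = {"id": parts[0]}
    if len(parts) > 1 and parts[1]:
        meta["morphospecies"] = parts[1]
    if len(parts) > 2 and parts[2]:
        meta["host_population"] = parts[2]
    if len(parts) > 3 and parts[3]:
        try:
            meta["genotype"] = int(parts[3].lstrip("GTgt") or parts[3])
        except ValueError as exc:
            raise InputError(f"bad genotype field in header {header!r}") from exc
    return meta


def read_alignment(path: str | Path, locus: str) -> AlignedSeqSet:
    """Read an aligned FASTA file; headers encode ``id|morphospecies|host|GT``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_header(rec.description.split()[0])
        records.append(
            SeqRecord(residues=str(rec.seq).upper(), locus=locus, **meta)
        )
    if not records:
        raise InputError(f"empty FASTA file: {path}")
    return AlignedSeqSet(locus=locus, records=records)


def write_alignment(seqs: AlignedSeqSet, path: str | Path) -> None:
    """Write FASTA with pipe-delimited metadata headers (round-trips reads)."""
    out = []
    for r in seqs:
        header = "|".join(
            [
                r.id,
                r.morphospecies or "",
                r.host_population or "",
                f"GT{r.genotype}" if r.genotype is not None else "",
            ]
        ).rstrip("|")
        out.append(BioSeqRecord(Seq(r.residues), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


def p_distance(a: SeqRecord, b: SeqRecord) -> float:
    """Percent p-distance with pairwise deletion of '-' and 'N' sites."""
    if len(a) != len(b):
        raise AlignmentError(
            f"length mismatch between {a.id!r} ({len(a)}) and {b.id!r} ({len(b)})"
        )
    if a.locus is not None and b.locus is not None and a.locus != b.locus:
        raise InputError(f"locus mismatch: {a.locus!r} vs {b.locus!r}")
    compared = 0
    mismatches = 0
    for x, y in zip(a.residues, b.residues):
        if x in _EXCLUDED or y in _EXCLUDED:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise UndefinedDistanceError(
            f"no comparable sites between {a.id!r} and {b.id!r}"
        )
    return 100.0 * mismatches / compared


@dataclass
class DivergenceMatrix:
    """Square symmetric percent-divergence matrix over labelled groups."""

    labels: list[str]
    values: np.ndarray
    statistic: str = "max"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise InputError("duplicate labels in divergence matrix")
        if not np.all(np.isfinite(self.values)):
            raise InputError("divergence matrix contains non-finite entries")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise InputError("divergence entries must lie in [0, 100]")
        if not np.allclose(self.values, self.values.T):
            raise InputError("divergence matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def max_off_diagonal(self) -> float:
        if len(self.labels) < 2:
            raise InputError("matrix has no off-diagonal entries")
        mask = ~np.eye(len(self.labels), dtype=bool)
        return float(self.values[mask].max())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path
        )

    @classmethod
    def from_csv(cls, path: str | Path, statistic: str = "max") -> "DivergenceMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.index]
        if labels != [str(x) for x in df.columns]:
            raise InputError("row and column labels differ in matrix CSV")
        return cls(labels=labels, values=df.to_numpy(dtype=float), statistic=statistic)


def divergence_matrix(
    seqs: AlignedSeqSet,
    group_by: str = "host_population",
    statistic: str = "max",
) -> DivergenceMatrix:
    """Between-group divergence matrix; diagonal holds within-group values.

    ``statistic`` summarises all cross-pair p-distances per group pair with
    ``max`` or ``mean``; a single-member group has within-group divergence 0.
    """
    if statistic not in ("max", "mean"):
        raise InputError(f"unknown statistic {statistic!r}")
    groups: dict[str, list[SeqRecord]] = {}
    for r in seqs:
        key = getattr(r, group_by)
        if key is None:
            raise InputError(f"record {r.id!r} has no {group_by!r} metadata")
        groups.setdefault(str(key), []).append(r)
    labels = sorted(groups)
    agg = np.max if statistic == "max" else np.mean
    n = len(labels)
    values = np.zeros((n, n))
    for i, g in enumerate(labels):
        within = [
            p_distance(a, b) for a, b in itertools.combinations(groups[g], 2)
        ]
        values[i, i] = agg(within) if within else 0.0
        for j in range(i + 1, n):
            h = labels[j]
            cross = [p_distance(a, b) for a in groups[g] for b in groups[h]]
            values[i, j] = values[j, i] = agg(cross)
    return DivergenceMatrix(labels=labels, values=values, statistic=statistic)
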