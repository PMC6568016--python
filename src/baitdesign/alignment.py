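"""Reading, validation, filtering and summarisation of gapped nucleotide alignments.

An :class:`Alignment` holds one gene's multiple sequence alignment: equal-length
rows over the IUPAC DNA alphabet plus ``-`` for gaps. Sequences are normalised
to uppercase with ``U`` mapped to ``T`` at read time, so a single internal
alphabet serves transcriptome- and genome-derived rows alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    DuplicateIdError,
    EmptyAlignmentError,
    InputError,
    ParameterError,
    TooFewSequencesError,
)

# Internal residue codes: A,C,G,T -> 0..3; ambiguity codes and N -> 4; gap -> 5.
GAP = "-"
A, C, G, T = 0, 1, 2, 3
AMBIG_CODE = 4
GAP_CODE = 5

_AMBIGUITY = "RYSWKMBDHVN"
_ALLOWED = set("ACGT") | set(_AMBIGUITY) | {GAP}

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
for _b in _AMBIGUITY:
    _CODE_TABLE[ord(_b)] = AMBIG_CODE
_CODE_TABLE[ord(GAP)] = GAP_CODE

_DECODE = np.frombuffer(b"ACGTN-", dtype=np.uint8)

def normalize_residues(residues: str) -> str:
    """Uppercase a residue string and map U/u to T."""
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned row: a unique id, optional taxon label, residue string."""

    id: str
    residues: str
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record id must be non-empty")
        residues = normalize_residues(self.residues)
        bad = set(residues) - _ALLOWED
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains illegal symbols: {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


def degap(rec: SequenceRecord | str) -> str:
    """Remove all gap characters from a record (or raw residue string)."""
    residues = rec.residues if isinstance(rec, SequenceRecord) else rec
    return residues.replace(GAP, "")


class Alignment:
    """An ordered, validated collection of equal-length sequence records."""

    def __init__(self, gene_id: str, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise TooFewSequencesError(
                f"alignment {gene_id!r} has {len(records)} record(s); need >= 2"
            )
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"alignment {gene_id!r} has records of unequal lengths {sorted(lengths)}"
            )
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"alignment {gene_id!r} has duplicate ids: {dupes}")
        self.gene_id = gene_id
        self.records = records
        self._codes: np.ndarray | None = None

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, id_: str) -> SequenceRecord:
        for r in self.records:
            if r.id == id_:
                return r
        raise KeyError(id_)

    def to_codes(self) -> np.ndarray:
        """Encode the alignment as an (n, n_columns) uint8 matrix.

        A,C,G,T -> 0..3, ambiguity/N -> 4, gap -> 5. Cached.
        """
        if self._codes is None:
            raw = np.frombuffer(
                "".join(r.residues for r in self.records).encode("ascii"),
                dtype=np.uint8,
            )
            self._codes = _CODE_TABLE[raw].reshape(len(self.records), self.n_columns)
        return self._codes


def codes_to_string(codes: np.ndarray) -> str:
    """Decode an internal code vector back into a residue string.

    Ambiguity detail is lost (all ambiguity codes decode to N); used by the
    synthetic generator, which never emits ambiguity codes other than N.
    """
    return _DECODE[codes].tobytes().decode("ascii")


def read_fasta_alignment(path: str | Path, gene_id: str | None = None) -> Alignment:
    """Read a gapped multi-FASTA alignment.

    Ids are taken as the full header token up to the first whitespace.
    ``gene_id`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Alignment(gene_id or path.stem, records)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as single-line-per-record FASTA."""
    with open(path, "w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_keep_list(path: str | Path) -> set[str]:
    """Read a taxon keep-list: one id per line, '#' starts a comment."""
    keep: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            keep.add(line)
    if not keep:
        raise InputError(f"keep-list {path} contains no ids")
    return keep


def filter_taxa(aln: Alignment, keep: Iterable[str]) -> Alignment:
    """Retain only records whose id is in ``keep``, preserving order."""
    keep = set(keep)
    if not keep:
        raise ParameterError("keep set must be non-empty")
    records = [r for r in aln.records if r.id in keep]
    if len(records) < 2:
        raise TooFewSequencesError(
            f"alignment {aln.gene_id!r}: only {len(records)} record(s) left after "
            "taxon filtering; need >= 2"
        )
    return Alignment(aln.gene_id, records)


def trim_gap_only_columns(aln: Alignment) -> Alignment:
    """Remove every column at which all records carry a gap."""
    codes = aln.to_codes()
    keep_cols = ~(codes == GAP_CODE).all(axis=0)
    if not keep_cols.any():
        raise EmptyAlignmentError(
            f"alignment {aln.gene_id!r} is gap-only; nothing left after trimming"
        )
    if keep_cols.all():
        return aln
    records = []
    for r in aln.records:
        raw = np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8)
        records.append(
            SequenceRecord(
                id=r.id,
                residues=raw[keep_cols].tobytes().decode("ascii"),
                taxon=r.taxon,
            )
        )
    return Alignment(aln.gene_id, records)


def count_variable_sites(aln: Alignment) -> tuple[int, int]:
    """Count total and variable columns of an alignment.

    A column is variable iff at least two distinct unambiguous nucleotides
    (A/C/G/T) occur in it; gaps, N, and ambiguity codes never create
    variability.
    """
    codes = aln.to_codes()
    present = np.stack([(codes == b).any(axis=0) for b in range(4)])
    variable = int((present.sum(axis=0) >= 2).sum())
    return aln.n_columns, variable
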