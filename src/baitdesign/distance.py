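"""Pairwise p-distances over shared non-gap sites.

The p-distance between two aligned rows is the fraction of mismatching sites
among *comparable* sites — positions where neither row carries a gap.
Positions at which either row has ``N`` or an IUPAC ambiguity code are also
excluded by default, so unresolvable states are never scored as matches or
mismatches. Pairs with no comparable sites at all are assigned the maximal
distance 1.0 in the matrix (such a pair genuinely cannot represent one
another) and a warning is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import _CODE_TABLE, Alignment, normalize_residues
from .errors import AlignmentShapeError, InputError

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`pairwise_p_distance` when two rows share no
#: comparable sites. Matrix assembly maps it to distance 1.0.
NO_OVERLAP = float("nan")


def _encode(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pairwise_p_distance(
    a: str,
    b: str,
    *,
    min_overlap: int = 1,
    ambiguous_as_missing: bool = True,
) -> tuple[float, int]:
    """p-distance and comparable-site count for two aligned residue strings.

    Returns ``(distance, overlap)``. When fewer than ``min_overlap`` sites are
    comparable the distance is the :data:`NO_OVERLAP` sentinel (NaN). Inputs
    are case- and U/T-insensitive.
    """
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"aligned strings differ in length ({len(a)} vs {len(b)})"
        )
    ca = _encode(normalize_residues(a))
    cb = _encode(normalize_residues(b))
    limit = 4 if ambiguous_as_missing else 5
    comparable = (ca < limit) & (cb < limit)
    overlap = int(comparable.sum())
    if overlap < max(min_overlap, 1):
        return NO_OVERLAP, overlap
    mismatches = int(((ca != cb) & comparable).sum())
    return mismatches / overlap, overlap


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with comparable-site bookkeeping.

    ``overlaps[i, j]`` is the number of comparable sites for pair (i, j);
    ``overlaps[i, i]`` is the number of scorable (non-gap, unambiguous)
    sites of row i. ``overlaps`` is None when the matrix was imported from a
    values-only TSV.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    overlaps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InputError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, id_: str) -> int:
        try:
            return self.ids.index(id_)
        except ValueError:
            raise KeyError(id_) from None

    def to_tsv(self, path: str | Path) -> None:
        """Export as a square TSV with an id header row and column."""
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, id_ in enumerate(self.ids):
                row = "\t".join(repr(float(v)) for v in self.values[i])
                fh.write(f"{id_}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        ids = tuple(lines[0].lstrip("\t").split("\t"))
        values = np.empty((len(ids), len(ids)))
        for i, line in enumerate(lines[1 : len(ids) + 1]):
            parts = line.split("\t")
            if parts[0] != ids[i]:
                raise InputError(f"row/column id mismatch at row {i}: {parts[0]!r}")
            values[i] = [float(x) for x in parts[1:]]
        return cls(ids=ids, values=values)


def build_distance_matrix(
    aln: Alignment,
    *,
    min_overlap: int = 1,
    ambiguous_as_missing: bool = True,
) -> DistanceMatrix:
    """All-pairs p-distance matrix for one alignment.

    Computed by one-hot matrix products, which is exact: every count is a sum
    of 0/1 terms well below float32's integer limit. Pairs with fewer than
    ``min_overlap`` comparable sites get distance 1.0 (logged).
    """
    codes = aln.to_codes()
    limit = 4 if ambiguous_as_missing else 5
    if not ambiguous_as_missing:
        # Scoring ambiguity symbols literally: distinct codes mismatch.
        pass
    valid = (codes < limit).astype(np.float32)
    n = len(aln)
    matches = np.zeros((n, n), dtype=np.float32)
    for b in range(limit):
        x = (codes == b).astype(np.float32)
        matches += x @ x.T
    overlaps = np.rint(valid @ valid.T).astype(np.int64)
    matches = np.rint(matches).astype(np.int64)
    mismatches = overlaps - matches

    values = np.ones((n, n), dtype=np.float64)
    ok = overlaps >= max(min_overlap, 1)
    values[ok] = mismatches[ok] / overlaps[ok]
    np.fill_diagonal(values, 0.0)

    n_no_overlap = int((~ok).sum() - (~ok.diagonal()).sum()) // 2
    if n_no_overlap:
        logger.warning(
            "alignment %s: %d sequence pair(s) share no comparable sites; "
            "assigned maximal distance 1.0",
            aln.gene_id,
            n_no_overlap,
        )
    return DistanceMatrix(ids=tuple(aln.ids), values=values, overlaps=overlaps)
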