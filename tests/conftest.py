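"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results character by character or by
exhaustive enumeration, sharing no code with the implementation paths they
check.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pytest

from baitdesign.alignment import Alignment, SequenceRecord

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

_NUC = set("ACGT")


def naive_p_distance(a: str, b: str) -> tuple[float | None, int]:
    """Character-by-character p-distance over unambiguous shared sites."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    comparable = 0
    mismatches = 0
    for x, y in zip(a, b, strict=True):
        if x in _NUC and y in _NUC:
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        return None, 0
    return mismatches / comparable, comparable


def exhaustive_kmedoids(D: np.ndarray, k: int) -> tuple[tuple[int, ...], float]:
    """Globally optimal medoid set by enumerating all subsets of size k."""
    n = D.shape[0]
    best_cost = np.inf
    best_set: tuple[int, ...] = ()
    for subset in itertools.combinations(range(n), k):
        cost = D[:, subset].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_set = subset
    return best_set, float(best_cost)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_genome_hits(
    probe: str, genome_seq: str, min_identity: float = 0.9
) -> int:
    """Hit loci by scanning every full-length window on both strands.

    Accepted windows (either strand) are merged when they overlap, matching
    the locus definition: one locus counts once.
    """
    L = len(probe)
    g = np.frombuffer(genome_seq.encode(), dtype=np.uint8)
    intervals: list[tuple[int, int]] = []
    for strand_probe in (probe, _revcomp(probe)):
        p = np.frombuffer(strand_probe.encode(), dtype=np.uint8)
        if g.size < L:
            continue
        mism = np.zeros(g.size - L + 1, dtype=np.int32)
        for off in range(L):
            mism += g[off : g.size - L + 1 + off] != p[off]
        for s in np.flatnonzero((L - mism) / L >= min_identity):
            intervals.append((int(s), int(s) + L))
    if not intervals:
        return 0
    intervals.sort()
    count = 1
    end = intervals[0][1]
    for s, e in intervals[1:]:
        if s >= end:
            count += 1
            end = e
        else:
            end = max(end, e)
    return count


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_alignment(rows: dict[str, str], gene_id: str = "gene1") -> Alignment:
    return Alignment(
        gene_id, [SequenceRecord(id=k, residues=v) for k, v in rows.items()]
    )


@pytest.fixture
def write_fasta(tmp_path: Path):
    """Write a {id: residues} dict as a FASTA file; returns the path."""

    def _write(rows: dict[str, str], name: str = "aln.fasta") -> Path:
        path = tmp_path / name
        with open(path, "w") as fh:
            for k, v in rows.items():
                fh.write(f">{k}\n{v}\n")
        return path

    return _write


def random_gapped_alignment(
    rng: np.random.Generator, n: int, length: int, gap_p: float = 0.15
) -> Alignment:
    """Uniform random alignment with i.i.d. gaps, for property tests."""
    alphabet = np.frombuffer(b"ACGT-", dtype=np.uint8)
    probs = [(1 - gap_p) / 4] * 4 + [gap_p]
    rows = {}
    for i in range(n):
        codes = rng.choice(5, size=length, p=probs)
        rows[f"s{i}"] = alphabet[codes].tobytes().decode()
    return make_alignment(rows)
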