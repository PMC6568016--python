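"""Synthetic alignments with planted divergence clusters, and genomes with
planted probe copies.

The generator emulates the structure of large per-gene transcriptome
alignments: tens to hundreds of rows, arbitrary gap blocks, and clusters of
related sequences separated by deep divergences. Each cluster descends from
its own ancestor; ancestors radiate from a common root so that every ancestor
pair sits at approximately ``between_divergence`` p-distance, and members
mutate from their ancestor at per-site rate ``within_divergence / 2`` so that
within-cluster pairwise p-distance concentrates near ``within_divergence``.
Mutations are substitutions only (uniform over the three alternative bases);
gaps enter as random blocks and never carry divergence signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alignment import Alignment, SequenceRecord, codes_to_string
from .errors import ParameterError
from .probes import Probe
from .specificity import Genome, reverse_complement

GAP_CODE = 5

# OneKP-like preset: the observed ranges of the real per-gene angiosperm
# alignments this generator stands in for.
ONEKP_SEQS_RANGE = (12, 655)
ONEKP_COLUMNS_RANGE = (105, 3498)

DEFAULT_MEMBERS_PER_CLUSTER = 10
DEFAULT_LENGTH = 600
DEFAULT_WITHIN = 0.05
DEFAULT_BETWEEN = 0.60
DEFAULT_GAP_FRACTION = 0.10


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated alignment for recovery tests."""

    n_clusters: int
    assignment: dict[str, int]  # sequence id -> cluster index
    within_divergence: float
    between_divergence: float
    seed: int


def _ancestor_rate(between: float) -> float:
    """Per-lineage mutation rate from the root giving pairwise divergence b.

    Two lineages mutating independently at rate m (uniform over the 3
    alternatives) differ at a site with probability 2m(1-m) + (2/3)m^2;
    solving for m gives m = (3 - sqrt(9 - 12 b)) / 4, valid for b <= 0.75.
    """
    return (3.0 - math.sqrt(9.0 - 12.0 * between)) / 4.0


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    n_mut = int(mask.sum())
    if n_mut:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def generate_clustered_alignment(
    n_clusters: int,
    members_per_cluster: int | Sequence[int] = DEFAULT_MEMBERS_PER_CLUSTER,
    length: int = DEFAULT_LENGTH,
    within_divergence: float = DEFAULT_WITHIN,
    between_divergence: float = DEFAULT_BETWEEN,
    gap_fraction: float = DEFAULT_GAP_FRACTION,
    seed: int = 0,
    gene_id: str = "synthgene",
) -> tuple[Alignment, PlantedTruth]:
    """Generate one alignment with ``n_clusters`` planted divergence clusters.

    ``members_per_cluster`` may be a single count or one count per cluster.
    Deterministic given ``seed``. Raises when ``between_divergence`` is below
    ``within_divergence`` (inseparable request) or out of range.
    """
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    if length < 1:
        raise ParameterError("length must be >= 1")
    if not 0 <= within_divergence < 1 or not 0 <= between_divergence < 1:
        raise ParameterError("divergences must be in [0, 1)")
    if n_clusters > 1 and between_divergence < within_divergence:
        raise ParameterError(
            "between_divergence must be >= within_divergence for planted clusters"
        )
    if not 0 <= gap_fraction < 0.5:
        raise ParameterError("gap_fraction must be in [0, 0.5)")
    if isinstance(members_per_cluster, int):
        members = [members_per_cluster] * n_clusters
    else:
        members = list(members_per_cluster)
    if len(members) != n_clusters or any(m < 1 for m in members):
        raise ParameterError("need one positive member count per cluster")

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=length).astype(np.uint8)
    if between_divergence >= 0.7499:
        # substitution saturation: independent ancestors (pairwise ~0.75)
        ancestors = [
            rng.integers(0, 4, size=length).astype(np.uint8) for _ in range(n_clusters)
        ]
    else:
        m = _ancestor_rate(between_divergence)
        ancestors = [_mutate(root, m, rng) for _ in range(n_clusters)]

    records: list[SequenceRecord] = []
    assignment: dict[str, int] = {}
    member_rate = within_divergence / 2.0
    gap_target = int(round(gap_fraction * length))
    for ci, anc in enumerate(ancestors):
        for mi in range(members[ci]):
            codes = _mutate(anc, member_rate, rng)
            if gap_target > 0:
                gapped = 0
                while gapped < gap_target:
                    start = int(rng.integers(0, length))
                    blen = int(rng.integers(1, 16))
                    stop = min(start + blen, length)
                    block = codes[start:stop]
                    gapped += int((block != GAP_CODE).sum())
                    block[:] = GAP_CODE
            sid = f"{gene_id}.c{ci:02d}.m{mi:03d}"
            records.append(SequenceRecord(id=sid, residues=codes_to_string(codes)))
            assignment[sid] = ci
    aln = Alignment(gene_id, records)
    truth = PlantedTruth(
        n_clusters=n_clusters,
        assignment=assignment,
        within_divergence=within_divergence,
        between_divergence=between_divergence,
        seed=seed,
    )
    return aln, truth


def sample_onekp_preset(rng: np.random.Generator) -> dict:
    """Draw one gene's generation parameters at the real data's scale.

    Row counts and column counts are drawn uniformly from the observed
    ranges; cluster counts from [5, 15] with members spread multinomially.
    """
    n_seqs = int(rng.integers(ONEKP_SEQS_RANGE[0], ONEKP_SEQS_RANGE[1] + 1))
    length = int(rng.integers(ONEKP_COLUMNS_RANGE[0], ONEKP_COLUMNS_RANGE[1] + 1))
    n_clusters = int(rng.integers(5, 16))
    n_clusters = min(n_clusters, n_seqs)
    # every cluster gets >=1 member; remainder spread uniformly
    extra = rng.multinomial(n_seqs - n_clusters, np.ones(n_clusters) / n_clusters)
    members = (extra + 1).tolist()
    return {
        "n_clusters": n_clusters,
        "members_per_cluster": members,
        "length": length,
        "within_divergence": DEFAULT_WITHIN,
        "between_divergence": DEFAULT_BETWEEN,
        "gap_fraction": DEFAULT_GAP_FRACTION,
    }


@dataclass(frozen=True)
class PlantedCopy:
    """Location of one planted probe copy in a synthetic genome."""

    probe_name: str
    start: int
    strand: str  # "+" | "-"


def generate_genome_with_inserts(
    probes: Sequence[Probe],
    copies: Mapping[Probe, int] | int,
    background_length: int,
    seed: int = 0,
    name: str = "synthetic_genome",
) -> tuple[Genome, list[PlantedCopy]]:
    """Uniform-background genome with probes planted non-overlappingly.

    ``copies`` maps each probe to its copy count (an int applies to all).
    Strand is random per copy. Returns the genome and the plant coordinates
    for oracle checks.
    """
    if isinstance(copies, int):
        copies = {p: copies for p in probes}
    total = sum(len(p) * copies.get(p, 0) for p in probes)
    if background_length < total:
        raise ParameterError(
            f"background_length {background_length} < total insert length {total}"
        )
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = bases[rng.integers(0, 4, size=background_length)].copy()
    occupied: list[tuple[int, int]] = []
    plants: list[PlantedCopy] = []
    for p in probes:
        L = len(p)
        for _ in range(copies.get(p, 0)):
            placed = False
            for _attempt in range(10000):
                s = int(rng.integers(0, background_length - L + 1))
                if all(s + L <= a or s >= b for a, b in occupied):
                    placed = True
                    break
            if not placed:
                raise ParameterError(
                    "could not place non-overlapping inserts; "
                    "increase background_length"
                )
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            seq = p.sequence if strand == "+" else reverse_complement(p.sequence)
            genome[s : s + L] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            occupied.append((s, s + L))
            plants.append(PlantedCopy(probe_name=p.name, start=s, strand=strand))
    return (
        Genome(name=name, sequences={f"{name}_seq": genome.tobytes().decode("ascii")}),
        plants,
    )
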