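"""Probe tiling, padding, N-run handling and deduplication.

Probes are fixed-length windows (default 120-mers) tiled across each target
instance at a uniform spacing of ``probe_length / tiling_density`` (default
40 bp, i.e. 3x tiling: every interior base is covered by three probes).
Instances shorter than one probe are padded at the 3' end with N to the probe
length; runs of 1–10 Ns are then replaced by Ts so short stretches of
ambiguity do not block synthesis, while longer N runs survive and any window
still containing N is dropped. Identical probe sequences arising from
different instances are collapsed to a single probe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParameterError
from .targets import TargetInstance

DEFAULT_PROBE_LENGTH = 120
DEFAULT_TILING_DENSITY = 3
DEFAULT_MAX_N_RUN = 10

_VALID_PROBE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Probe:
    """A fully specified fixed-length oligo with provenance."""

    gene_id: str
    source_id: str
    start: int  # 0-based offset into the processed (padded) instance sequence
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError("probe start must be >= 0")
        if not _VALID_PROBE.match(self.sequence):
            raise ParameterError(
                f"probe {self.name}: sequence must be over A/C/G/T only"
            )

    @property
    def name(self) -> str:
        return f"{self.gene_id}_{self.source_id}_{self.start}"

    def __len__(self) -> int:
        return len(self.sequence)


def pad_short_sequence(seq: str, probe_length: int = DEFAULT_PROBE_LENGTH) -> str:
    """Pad a sequence shorter than one probe with 3'-terminal Ns."""
    if not seq:
        raise ParameterError("cannot pad an empty sequence")
    if len(seq) >= probe_length:
        return seq
    return seq + "N" * (probe_length - len(seq))


def replace_short_N_runs(seq: str, max_run: int = DEFAULT_MAX_N_RUN) -> str:
    """Replace each maximal run of 1..max_run Ns with Ts; longer runs survive."""
    return re.sub(
        "N+", lambda m: "T" * len(m.group()) if len(m.group()) <= max_run else m.group(), seq
    )


def tile_starts(length: int, probe_length: int, step: int) -> list[int]:
    """Window start offsets: 0, step, 2*step, ... plus an end-anchored extra.

    When ``length - probe_length`` is not a multiple of ``step`` one extra
    window anchored at the 3' end guarantees full terminal coverage.
    """
    last = length - probe_length
    starts = list(range(0, last + 1, step))
    if last % step != 0:
        starts.append(last)
    return starts


def prepare_instance_sequence(
    instance: TargetInstance,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    max_n_run: int = DEFAULT_MAX_N_RUN,
) -> str:
    """Pad to probe length and apply the short-N-run replacement."""
    return replace_short_N_runs(
        pad_short_sequence(instance.sequence, probe_length), max_run=max_n_run
    )


def tile_probes(
    instance: TargetInstance,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    tiling_density: int = DEFAULT_TILING_DENSITY,
    max_n_run: int = DEFAULT_MAX_N_RUN,
) -> list[Probe]:
    """Tile probes across one target instance.

    The instance is padded and N-processed first. Windows still containing N
    (from runs longer than ``max_n_run``) are dropped; use
    :meth:`ProbeSet.from_instances` to also account for how many.
    """
    if probe_length % tiling_density != 0:
        raise ParameterError(
            f"tiling_density {tiling_density} does not divide probe_length {probe_length}"
        )
    seq = prepare_instance_sequence(instance, probe_length, max_n_run)
    step = probe_length // tiling_density
    probes = []
    for s in tile_starts(len(seq), probe_length, step):
        window = seq[s : s + probe_length]
        if "N" in window:
            continue
        probes.append(
            Probe(
                gene_id=instance.gene_id,
                source_id=instance.source_id,
                start=s,
                sequence=window,
            )
        )
    return probes


@dataclass
class ProbeSet:
    """A deduplicated probe collection plus bookkeeping counters."""

    probes: list[Probe] = field(default_factory=list)
    duplicates_removed: int = 0
    n_windows_dropped: int = 0

    def __len__(self) -> int:
        return len(self.probes)

    @classmethod
    def from_instances(
        cls,
        instances: Iterable[TargetInstance],
        probe_length: int = DEFAULT_PROBE_LENGTH,
        tiling_density: int = DEFAULT_TILING_DENSITY,
        max_n_run: int = DEFAULT_MAX_N_RUN,
    ) -> "ProbeSet":
        """Tile every instance, count dropped windows, deduplicate."""
        raw: list[Probe] = []
        dropped = 0
        step = probe_length // tiling_density
        for inst in instances:
            seq = prepare_instance_sequence(inst, probe_length, max_n_run)
            expected = len(tile_starts(len(seq), probe_length, step))
            probes = tile_probes(inst, probe_length, tiling_density, max_n_run)
            dropped += expected - len(probes)
            raw.extend(probes)
        out = deduplicate(raw)
        out.n_windows_dropped = dropped
        return out

    def write_fasta(self, path: str | Path) -> None:
        """Probe FASTA: header geneID_sourceID_start, single-line sequences."""
        with open(path, "w") as fh:
            for p in self.probes:
                fh.write(f">{p.name}\n{p.sequence}\n")


def deduplicate(probes: "Sequence[Probe] | ProbeSet") -> ProbeSet:
    """Collapse exact sequence duplicates, keeping the first occurrence.

    'First' is in (gene_id, source_id, start) order, so the retained probe is
    independent of input ordering.
    """
    if isinstance(probes, ProbeSet):
        probes = probes.probes
    lengths = {len(p) for p in probes}
    if len(lengths) > 1:
        raise ParameterError(f"mixed probe lengths {sorted(lengths)} in one set")
    ordered = sorted(probes, key=lambda p: (p.gene_id, p.source_id, p.start))
    seen: dict[str, Probe] = {}
    removed = 0
    for p in ordered:
        if p.sequence in seen:
            removed += 1
        else:
            seen[p.sequence] = p
    return ProbeSet(probes=list(seen.values()), duplicates_removed=removed)


def read_probe_fasta(path: str | Path) -> ProbeSet:
    """Re-read a probe FASTA written by :meth:`ProbeSet.write_fasta`.

    Headers are parsed as geneID_sourceID_start; the gene id must not itself
    contain an underscore.
    """
    probes: list[Probe] = []
    header: str | None = None
    seqs: list[str] = []

    def flush() -> None:
        if header is None:
            return
        gene, rest = header.split("_", 1)
        source, start = rest.rsplit("_", 1)
        probes.append(
            Probe(gene_id=gene, source_id=source, start=int(start), sequence="".join(seqs))
        )

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0]
            seqs = []
        elif line.strip():
            seqs.append(line.strip().upper())
    flush()
    return ProbeSet(probes=probes)
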