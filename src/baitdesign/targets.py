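"""Assembly of target instances: degapped representatives plus mandatory references.

After medoid selection, each chosen alignment row is degapped into a *target
instance* — the concrete coding sequence probes are tiled from. Well-annotated
genome orthologs (e.g. Arabidopsis thaliana, Oryza sativa, Amborella
trichopoda rows of the same alignment) can be injected as mandatory instances
when the medoids did not already pick them, so every gene carries a reference
gene model spanning deep divergences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .alignment import Alignment, degap
from .errors import DegenerateSequenceError, MissingSequenceError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetInstance:
    """One degapped representative coding sequence of one gene."""

    gene_id: str
    source_id: str
    sequence: str
    origin: str  # "medoid" | "mandatory_reference"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DegenerateSequenceError(
                f"{self.source_id} ({self.gene_id}): empty sequence after degapping"
            )
        if "-" in self.sequence:
            raise DegenerateSequenceError(
                f"{self.source_id} ({self.gene_id}): gap in degapped sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def header(self) -> str:
        """HybPiper-style target header: SourceID-GeneID, source first."""
        return f"{self.source_id}-{self.gene_id}"


def add_mandatory_references(
    medoid_ids: Sequence[str],
    reference_ids: Sequence[str],
    aln: Alignment,
) -> list[str]:
    """Union of medoid ids and reference ids present in the alignment.

    Medoid order is preserved, then references in their given order.
    Membership is by sequence identifier. References absent from the
    alignment are skipped with a warning.
    """
    out = list(medoid_ids)
    seen = set(out)
    present = set(aln.ids)
    for rid in reference_ids:
        if rid in seen:
            continue
        if rid not in present:
            logger.warning(
                "gene %s: mandatory reference %r not in alignment; skipped",
                aln.gene_id,
                rid,
            )
            continue
        out.append(rid)
        seen.add(rid)
    return out


def build_target_instances(
    aln: Alignment,
    ids: Sequence[str],
    origins: dict[str, str] | None = None,
) -> list[TargetInstance]:
    """Degap the selected alignment rows into target instances, order preserved.

    ``origins`` maps id -> origin tag; ids not in the map are "medoid".
    """
    present = set(aln.ids)
    missing = [i for i in ids if i not in present]
    if missing:
        raise MissingSequenceError(
            f"gene {aln.gene_id!r}: ids not in alignment: {missing}"
        )
    origins = origins or {}
    return [
        TargetInstance(
            gene_id=aln.gene_id,
            source_id=i,
            sequence=degap(aln[i]),
            origin=origins.get(i, "medoid"),
        )
        for i in ids
    ]


def mean_target_length(instances: Sequence[TargetInstance]) -> float:
    """Arithmetic mean of degapped instance lengths for one gene."""
    if not instances:
        raise ParameterError("mean_target_length needs at least one instance")
    return sum(len(t) for t in instances) / len(instances)


def write_target_fasta(instances: Iterable[TargetInstance], path: str | Path) -> None:
    """Write the pooled target file: 'SourceID-GeneID' headers, unwrapped."""
    with open(path, "w") as fh:
        for t in instances:
            fh.write(f">{t.header}\n{t.sequence}\n")


def read_reference_map(path: str | Path) -> dict[str, list[str]]:
    """Read a gene -> mandatory reference ids map.

    YAML mapping (gene: [id, ...]) or two-column TSV 'gene<TAB>id1,id2'.
    """
    import yaml

    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = None
    if isinstance(data, dict):
        return {
            str(g): [str(v)] if isinstance(v, str) else [str(x) for x in v]
            for g, v in data.items()
        }
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        gene, ids = line.split("\t", 1)
        out[gene] = [x.strip() for x in ids.split(",") if x.strip()]
    return out
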