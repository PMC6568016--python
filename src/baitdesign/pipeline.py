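"""End-to-end probe design across a directory of gene alignments.

Per gene: optional taxon filtering, gap-only column trimming, p-distance
matrix, minimal-k medoid selection, mandatory-reference injection, degapped
target instances and probe tiling. Pooled probes are deduplicated and, when
reference genomes are supplied, screened for promiscuous matches. Outputs are
a probe FASTA, a HybPiper-style target FASTA, a per-gene report TSV and a
specificity removal TSV. Runs are deterministic: genes are processed in
lexicographic order and per-gene seeds derive from the master seed and the
gene id, so results do not depend on directory listing order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .alignment import (
    Alignment,
    count_variable_sites,
    filter_taxa,
    read_fasta_alignment,
    trim_gap_only_columns,
)
from .distance import build_distance_matrix
from .errors import BaitDesignError, InputError
from .medoids import (
    MedoidSolution,
    SelectionParams,
    coverage_fraction,
    derive_seed,
    evaluate_reference_set,
    select_minimal_medoids,
)
from .probes import (
    DEFAULT_MAX_N_RUN,
    DEFAULT_PROBE_LENGTH,
    DEFAULT_TILING_DENSITY,
    ProbeSet,
    tile_probes,
)
from .specificity import DEFAULT_MIN_IDENTITY, FilterResult, Genome, filter_promiscuous
from .targets import (
    TargetInstance,
    add_mandatory_references,
    build_target_instances,
    mean_target_length,
    write_target_fasta,
)

logger = logging.getLogger(__name__)

ALIGNMENT_SUFFIXES = (".fasta", ".fa", ".fna", ".aln")

REPORT_COLUMNS = [
    "gene_id",
    "n_sequences",
    "n_columns",
    "k",
    "coverage",
    "cost",
    "status",
    "restarts_used",
    "seed",
    "n_target_instances",
    "mean_target_length",
    "n_probes_raw",
    "n_probes_final",
]


@dataclass
class PipelineConfig:
    """Effective configuration of one design run."""

    selection: SelectionParams = field(default_factory=SelectionParams)
    probe_length: int = DEFAULT_PROBE_LENGTH
    tiling_density: int = DEFAULT_TILING_DENSITY
    max_n_run: int = DEFAULT_MAX_N_RUN
    min_identity: float = DEFAULT_MIN_IDENTITY
    reference_map: dict[str, list[str]] = field(default_factory=dict)
    genome_paths: tuple[str, ...] = ()
    keep_ids: frozenset[str] | None = None
    trim: bool = True
    min_overlap_sites: int = 1

    def to_metadata(self) -> dict[str, str]:
        sel = dataclasses.asdict(self.selection)
        meta = {f"selection.{k}": str(v) for k, v in sel.items()}
        meta.update(
            {
                "probe_length": str(self.probe_length),
                "tiling_density": str(self.tiling_density),
                "max_n_run": str(self.max_n_run),
                "min_identity": str(self.min_identity),
                "trim": str(self.trim),
                "min_overlap_sites": str(self.min_overlap_sites),
                "n_genomes": str(len(self.genome_paths)),
                "version": __version__,
            }
        )
        return meta


@dataclass
class PipelineReport:
    """Per-gene rows plus global totals and run metadata."""

    per_gene: pd.DataFrame
    totals: dict[str, float]
    metadata: dict[str, str]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}={v}\n")
            for k, v in sorted(self.totals.items()):
                fh.write(f"# total.{k}={v}\n")
            self.per_gene.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def find_alignment_files(alignment_dir: str | Path) -> list[Path]:
    alignment_dir = Path(alignment_dir)
    if not alignment_dir.is_dir():
        raise InputError(f"alignment directory not found: {alignment_dir}")
    files = sorted(
        (p for p in alignment_dir.iterdir() if p.suffix.lower() in ALIGNMENT_SUFFIXES),
        key=lambda p: p.stem,
    )
    if not files:
        raise InputError(f"no alignment files (*.fasta/*.fa/*.fna) in {alignment_dir}")
    return files


def _load_gene(path: Path, config: PipelineConfig) -> Alignment:
    aln = read_fasta_alignment(path)
    if config.keep_ids:
        aln = filter_taxa(aln, config.keep_ids)
    if config.trim:
        aln = trim_gap_only_columns(aln)
    return aln


def _design_gene(
    aln: Alignment, config: PipelineConfig, gene_seed: int
) -> tuple[MedoidSolution, list[TargetInstance], list]:
    params = dataclasses.replace(config.selection, seed=gene_seed)
    dm = build_distance_matrix(aln, min_overlap=config.min_overlap_sites)
    sol = select_minimal_medoids(dm, params, gene_id=aln.gene_id)
    if not sol.passed:
        return sol, [], []
    refs = config.reference_map.get(aln.gene_id, [])
    ids = add_mandatory_references(list(sol.medoid_ids), refs, aln)
    origins = {
        i: "mandatory_reference" for i in ids if i not in set(sol.medoid_ids)
    }
    instances = build_target_instances(aln, ids, origins)
    raw_probes = []
    for inst in instances:
        raw_probes.extend(
            tile_probes(
                inst, config.probe_length, config.tiling_density, config.max_n_run
            )
        )
    return sol, instances, raw_probes


def run_pipeline(
    alignment_dir: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> PipelineReport:
    """Design probes for every alignment in a directory; write all outputs.

    Unreadable or invalid alignments are logged, marked ``errored`` in the
    report, and do not stop the run. Genes failing the coverage criterion
    contribute no probes but appear in the report.
    """
    files = find_alignment_files(alignment_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    all_instances: list[TargetInstance] = []
    master_seed = config.selection.seed

    for path in files:
        gene_id = path.stem
        gene_seed = derive_seed(master_seed, gene_id)
        row: dict = {c: "" for c in REPORT_COLUMNS}
        row["gene_id"] = gene_id
        try:
            aln = _load_gene(path, config)
            sol, instances, raw_probes = _design_gene(aln, config, gene_seed)
        except BaitDesignError as exc:
            logger.error("gene %s: %s", gene_id, exc)
            row.update(status="errored")
            rows.append(row)
            continue
        row.update(
            n_sequences=len(aln),
            n_columns=aln.n_columns,
            k=sol.k,
            coverage=sol.coverage,
            cost=sol.cost,
            status=sol.status,
            restarts_used=sol.restarts_used,
            seed=sol.seed,
            n_target_instances=len(instances),
            mean_target_length=mean_target_length(instances) if instances else 0.0,
            n_probes_raw=len(raw_probes),
        )
        logger.info(
            "gene %s: n=%d status=%s k=%d coverage=%.3f",
            gene_id,
            len(aln),
            sol.status,
            sol.k,
            sol.coverage,
        )
        rows.append(row)
        all_instances.extend(instances)

    pooled = ProbeSet.from_instances(
        all_instances,
        config.probe_length,
        config.tiling_density,
        config.max_n_run,
    )

    removals: FilterResult | None = None
    if config.genome_paths:
        genomes = [Genome.from_fasta(p) for p in config.genome_paths]
        removals = filter_promiscuous(pooled, genomes, config.min_identity)
        final = removals.probe_set
        final.duplicates_removed = pooled.duplicates_removed
        final.n_windows_dropped = pooled.n_windows_dropped
    else:
        final = pooled

    final_per_gene: dict[str, int] = {}
    for p in final.probes:
        final_per_gene[p.gene_id] = final_per_gene.get(p.gene_id, 0) + 1
    for row in rows:
        if row["status"] == "passed":
            row["n_probes_final"] = final_per_gene.get(row["gene_id"], 0)
        elif row["status"] != "errored":
            row["n_probes_final"] = 0

    per_gene = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    passed = [r for r in rows if r["status"] == "passed"]
    totals = {
        "genes_passed": len(passed),
        "genes_failed": len(rows) - len(passed),
        "total_target_instances": int(sum(r["n_target_instances"] or 0 for r in passed)),
        "total_targeted_length": float(sum(r["mean_target_length"] or 0.0 for r in passed)),
        "total_probes": len(final),
        "duplicates_removed": final.duplicates_removed,
        "windows_dropped": final.n_windows_dropped,
        "probes_removed_by_specificity": (
            sum(1 for r in removals.reports if r.removed) if removals else 0
        ),
    }
    report = PipelineReport(
        per_gene=per_gene,
        totals=totals,
        metadata={**config.to_metadata(), "seed": str(master_seed)},
    )

    final.write_fasta(out_dir / "probes.fasta")
    write_target_fasta(all_instances, out_dir / "targets.fasta")
    report.write_tsv(out_dir / "report.tsv")
    if removals is not None:
        removals.to_frame().to_csv(out_dir / "removals.tsv", sep="\t", index=False)
    if totals["genes_passed"] == 0:
        logger.error("no gene passed the coverage criterion")
    return report


def compare_medoid_vs_reference(
    alignment_dir: str | Path,
    reference_map: dict[str, Sequence[str]],
    params: SelectionParams,
    *,
    trim: bool = True,
) -> pd.DataFrame:
    """Per-gene coverage by selected medoids vs by fixed reference sequences.

    Rows whose gene has no resolvable reference id are flagged
    (``reference_resolved = False``) with NaN reference coverage, not dropped.
    """
    files = find_alignment_files(alignment_dir)
    config = PipelineConfig(selection=params, trim=trim)
    rows = []
    for path in files:
        gene_id = path.stem
        aln = _load_gene(path, config)
        dm = build_distance_matrix(aln)
        gene_params = dataclasses.replace(params, seed=derive_seed(params.seed, gene_id))
        sol = select_minimal_medoids(dm, gene_params, gene_id=gene_id)
        med_idx = [dm.index(i) for i in sol.medoid_ids]
        cov_med = coverage_fraction(dm, med_idx, params.divergence_threshold)
        refs = [r for r in reference_map.get(gene_id, []) if r in dm.ids]
        if refs and len(refs) < dm.n:
            cov_ref = evaluate_reference_set(dm, refs, params.divergence_threshold)
            resolved = True
        else:
            cov_ref = float("nan")
            resolved = False
        rows.append(
            {
                "gene_id": gene_id,
                "n_sequences": dm.n,
                "k": sol.k,
                "status": sol.status,
                "coverage_medoid": cov_med,
                "coverage_reference": cov_ref,
                "reference_resolved": resolved,
            }
        )
    return pd.DataFrame(rows)


def variable_sites_table(
    alignment_dir: str | Path,
    keep_ids: frozenset[str] | None = None,
    *,
    trim: bool = False,
) -> pd.DataFrame:
    """Per-gene variable-character counts (within-group variability summary).

    ``trim`` controls whether columns that are gap-only within the retained
    taxa are removed before counting; by default totals reflect the full
    alignment length.
    """
    files = find_alignment_files(alignment_dir)
    rows = []
    for path in files:
        aln = read_fasta_alignment(path)
        if keep_ids:
            aln = filter_taxa(aln, keep_ids)
        if trim:
            aln = trim_gap_only_columns(aln)
        total, variable = count_variable_sites(aln)
        rows.append(
            {
                "gene_id": aln.gene_id,
                "n_taxa": len(aln),
                "total_sites": total,
                "variable_sites": variable,
            }
        )
    return pd.DataFrame(rows)
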