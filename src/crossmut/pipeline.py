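"""End-to-end pipeline driver: call → QC → integrate → rank → report.

The driver reads the assembly and one mpileup per mutant line, calls SNVs,
summarises every line, excludes contaminant-flagged lines (the surviving
cohort is re-integrated without them), applies the shared-position filter,
counts mutated lines per contig, flags assembly artifacts from the optional
wild-type self-mapping, and writes the candidate report, histogram and QC
tables plus a manifest echoing every threshold used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .candidate_ranker import (
    apply_artifact_flags,
    integrate,
    report_candidates,
    shared_position_filter,
    write_candidates_tsv,
    write_histogram_tsv,
)
from .errors import ConfigError
from .formats_io import read_fasta, read_mpileup
from .qc import (
    DEFAULT_ARTIFACT_PER_KB,
    DEFAULT_CONTAMINANT_RATIO,
    flag_contaminants,
    summarize_mutant,
    wildtype_self_check,
    write_artifacts_tsv,
    write_qc_tsv,
)
from .snv_caller import FilterConfig, call_mutant_snvs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    assembly_path: Path
    pileup_paths: dict  # mutant_id -> path
    out_dir: Path
    wt_pileup_path: Optional[Path] = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    contaminant_ratio: float = DEFAULT_CONTAMINANT_RATIO
    artifact_per_kb: float = DEFAULT_ARTIFACT_PER_KB

    def validate(self) -> None:
        if not Path(self.assembly_path).exists():
            raise ConfigError(f"assembly not found: {self.assembly_path}")
        if not self.pileup_paths:
            raise ConfigError("no mutant pileup paths given")
        for mutant_id, path in self.pileup_paths.items():
            if not Path(path).exists():
                raise ConfigError(f"pileup for {mutant_id!r} not found: {path}")
        if self.wt_pileup_path is not None and not Path(self.wt_pileup_path).exists():
            raise ConfigError(f"wild-type pileup not found: {self.wt_pileup_path}")


@dataclass
class PipelineResult:
    summaries: list
    excluded_mutants: list
    artifact_contigs: set
    reports: list
    histogram: object
    candidates: list


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write report files under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    assembly = read_fasta(config.assembly_path)
    logger.info("assembly: %d contigs, %d bp", len(assembly),
                sum(c.length for c in assembly))

    callsets = []
    for mutant_id in sorted(config.pileup_paths):
        path = config.pileup_paths[mutant_id]
        callset = call_mutant_snvs(
            read_mpileup(path, assembly), assembly, config.filters, mutant_id
        )
        logger.info("%s: %d SNVs over %d callable bases",
                    mutant_id, callset.n_calls, callset.callable_bases)
        callsets.append(callset)

    # Densities are measured on shared-position-filtered calls: positions
    # carried by many lines (pre-existing variation, artifact divergence)
    # are discarded before any per-line statistic, so they cannot mask a
    # contaminant's excess density.
    prefiltered = shared_position_filter(callsets, config.filters)
    summaries = flag_contaminants(
        [summarize_mutant(cs) for cs in prefiltered], config.contaminant_ratio
    )
    excluded = [s.mutant_id for s in summaries if s.contaminant_flag]
    for mutant_id in excluded:
        logger.warning("excluding contaminant-flagged line %s", mutant_id)
    kept = [cs for cs in callsets if cs.mutant_id not in excluded]
    if not kept:
        raise ConfigError("every line was contaminant-flagged; nothing to integrate")

    artifact_ids: set = set()
    if config.wt_pileup_path is not None:
        artifact_ids = wildtype_self_check(
            read_mpileup(config.wt_pileup_path, assembly),
            assembly, config.filters, config.artifact_per_kb,
        )
        logger.info("wild-type self-check flagged %d artifact contig(s)", len(artifact_ids))
    else:
        logger.warning("no wild-type self-mapping pileup: artifact check skipped")

    filtered = shared_position_filter(kept, config.filters)
    reports, histogram = integrate(filtered, assembly, config.filters)
    apply_artifact_flags(reports, artifact_ids)
    candidates = report_candidates(reports, config.filters)

    write_qc_tsv(summaries, out / "qc.tsv")
    write_artifacts_tsv(artifact_ids, out / "artifact_contigs.tsv")
    write_candidates_tsv(candidates, out / "candidates.tsv")
    write_histogram_tsv(histogram, out / "histogram.tsv")
    manifest = {
        "version": __version__,
        "assembly": str(config.assembly_path),
        "pileups": {m: str(p) for m, p in sorted(config.pileup_paths.items())},
        "wildtype_pileup": str(config.wt_pileup_path) if config.wt_pileup_path else None,
        "filters": {
            "min_coverage": config.filters.min_coverage,
            "min_allele_frequency": config.filters.min_allele_frequency,
            "max_mutants_sharing_position": config.filters.max_mutants_sharing_position,
            "min_mutants_per_contig": config.filters.min_mutants_per_contig,
            "contaminant_ratio": config.contaminant_ratio,
            "artifact_per_kb": config.artifact_per_kb,
        },
        "excluded_contaminants": excluded,
        "artifact_contigs": sorted(artifact_ids),
        "n_candidates": len(candidates),
    }
    with open(out / "manifest.yaml", "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)

    return PipelineResult(summaries, excluded, artifact_ids, reports, histogram, candidates)
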