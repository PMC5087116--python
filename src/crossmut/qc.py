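"""Cohort quality control: contaminant lines and assembly artifacts.

Two failure modes masquerade as mutants. A cultivar contaminant — a line
not descended from the mutagenised parent — shows orders of magnitude more
SNVs than the EMS expectation (observed contrast: one SNV per ~1.6 kb
versus one per several hundred kb) with a mixed substitution spectrum. A
mis-assembled (e.g. chimeric) contig disagrees with the wild type's *own*
reads, so mapping the wild-type data back to the assembly and counting
near-fixed disagreements per unmasked kilobase exposes it.

Both decisions here use explicit numeric thresholds exposed in
configuration: a line is flagged when its bases-per-SNV density is more
than ``ratio_threshold`` (default 20×) below the cohort median, and a
contig is flagged when its fixed wild-type disagreements exceed
``disagreement_per_kb_threshold`` (default 0.5) per unmasked kb. Both
defaults sit far from the extremes they separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .formats_io import PileupColumn, ReferenceContig, assembly_index
from .snv_caller import FilterConfig, MutantCallSet, call_mutant_snvs, spectrum

logger = logging.getLogger(__name__)

DEFAULT_CONTAMINANT_RATIO = 20.0
DEFAULT_ARTIFACT_PER_KB = 0.5


@dataclass(frozen=True)
class MutantSummary:
    """Density and spectrum summary of one mutant line.

    ``bases_per_snv`` is None (reported absent, never infinite) for a line
    with zero calls.
    """

    mutant_id: str
    n_snvs: int
    callable_bases: int
    bases_per_snv: Optional[float]
    canonical_fraction: Optional[float]
    contaminant_flag: bool = False


def summarize_mutant(callset: MutantCallSet) -> MutantSummary:
    """SNV density (callable bases per SNV) and canonical-spectrum fraction."""
    n = callset.n_calls
    return MutantSummary(
        mutant_id=callset.mutant_id,
        n_snvs=n,
        callable_bases=callset.callable_bases,
        bases_per_snv=callset.callable_bases / n if n else None,
        canonical_fraction=spectrum(callset),
    )


def flag_contaminants(
    summaries: Sequence[MutantSummary],
    ratio_threshold: float = DEFAULT_CONTAMINANT_RATIO,
) -> list[MutantSummary]:
    """Flag lines whose SNV density is ``ratio_threshold``-fold above the cohort.

    A line is a contaminant candidate when its bases_per_snv falls below
    (cohort median bases_per_snv) / ratio_threshold. With fewer than three
    summaries there is no meaningful cohort and QC is skipped with a warning.
    """
    if len(summaries) < 3:
        logger.warning(
            "contaminant QC skipped: need ≥3 mutant lines, got %d", len(summaries)
        )
        return list(summaries)
    densities = [s.bases_per_snv for s in summaries if s.bases_per_snv is not None]
    if not densities:
        return list(summaries)
    cutoff = median(densities) / ratio_threshold
    return [
        replace(s, contaminant_flag=(s.bases_per_snv is not None and s.bases_per_snv < cutoff))
        for s in summaries
    ]


def wildtype_self_check(
    wt_pileup: Iterable[PileupColumn],
    assembly: Union[Sequence[ReferenceContig], Mapping[str, ReferenceContig]],
    config: FilterConfig,
    disagreement_per_kb_threshold: float = DEFAULT_ARTIFACT_PER_KB,
) -> set:
    """Flag contigs whose own wild-type reads disagree with the assembly.

    Runs the SNV caller on the wild-type self-mapping pileup: positions with
    depth ≥ min_coverage where a non-reference base is near-fixed are counted
    per contig, and contigs exceeding the threshold per unmasked kb are
    returned as assembly artifacts.
    """
    index = assembly_index(assembly)
    callset = call_mutant_snvs(wt_pileup, index, config, "wildtype")
    per_contig: dict = {}
    for call in callset.calls:
        per_contig[call.contig_id] = per_contig.get(call.contig_id, 0) + 1
    flagged = set()
    for cid, n_disagreements in per_contig.items():
        unmasked_kb = index[cid].unmasked_bases / 1000.0
        if unmasked_kb > 0 and n_disagreements / unmasked_kb > disagreement_per_kb_threshold:
            flagged.add(cid)
    return flagged


def write_qc_tsv(summaries: Sequence[MutantSummary], path) -> None:
    frame = pd.DataFrame(
        [
            (s.mutant_id, s.n_snvs, s.callable_bases,
             "" if s.bases_per_snv is None else round(s.bases_per_snv, 1),
             "" if s.canonical_fraction is None else round(s.canonical_fraction, 4),
             int(s.contaminant_flag))
            for s in summaries
        ],
        columns=["mutant_id", "n_snvs", "callable_bases", "bases_per_snv",
                 "canonical_fraction", "contaminant_flag"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_artifacts_tsv(artifact_ids: Iterable[str], path) -> None:
    frame = pd.DataFrame(sorted(artifact_ids), columns=["contig"])
    frame.to_csv(path, sep="\t", index=False)
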