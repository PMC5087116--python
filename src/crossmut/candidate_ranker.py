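"""Cross-mutant integration and contig ranking.

The causal contig carries an independently induced lesion in every true
mutant line, while chance background mutations rarely hit the same contig
in more than a couple of lines. Integration therefore counts, per assembly
contig, how many mutant lines carry at least one surviving SNV on it; the
resulting count histogram is the headline summary of an experiment, and
contigs mutated in at least ``min_mutants_per_contig`` lines are reported
as candidates.

A position-level filter runs first: any single position mutated in more
than ``max_mutants_sharing_position`` distinct lines is discarded from all
of them, because independent EMS hits essentially never coincide — shared
positions indicate pre-existing (cultivar) variation or mapping error.

Ranking is deterministic: mutant count descending, then total SNVs
descending, then contig id ascending.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple, Union

import pandas as pd

from .errors import IntegrityError, ValidationError
from .formats_io import ReferenceContig, assembly_index
from .snv_caller import FilterConfig, MutantCallSet, SnvCall


@dataclass
class ContigReport:
    """Cross-mutant evidence for one assembly contig."""

    contig_id: str
    per_mutant_snvs: dict  # mutant_id -> list[SnvCall]
    n_mutants_mutated: int
    total_snvs: int
    is_candidate: bool
    artifact_flag: bool = False


@dataclass
class ContigHistogram:
    """Number of contigs mutated in exactly k mutant lines, k = 0..n_mutants."""

    counts: dict  # k -> number of contigs
    n_contigs_total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_contigs_total:
            raise IntegrityError("histogram counts do not sum to the contig total")


def shared_position_filter(
    callsets: Sequence[MutantCallSet], config: FilterConfig
) -> list[MutantCallSet]:
    """Drop every position mutated in more than ``max_mutants_sharing_position``
    distinct mutants, from all call sets; everything else passes unchanged."""
    if not callsets:
        raise ValidationError("shared_position_filter needs at least one call set")
    carriers: dict = defaultdict(set)
    for cs in callsets:
        for call in cs.calls:
            carriers[(call.contig_id, call.position)].add(cs.mutant_id)
    shared = {
        key
        for key, mutants in carriers.items()
        if len(mutants) > config.max_mutants_sharing_position
    }
    if not shared:
        return list(callsets)
    return [
        MutantCallSet(
            cs.mutant_id,
            [c for c in cs.calls if (c.contig_id, c.position) not in shared],
            cs.callable_bases,
        )
        for cs in callsets
    ]


def integrate(
    callsets: Sequence[MutantCallSet],
    assembly: Union[Sequence[ReferenceContig], Mapping[str, ReferenceContig]],
    config: FilterConfig,
) -> Tuple[list[ContigReport], ContigHistogram]:
    """Count mutated mutants per contig and build the count histogram.

    Every assembly contig gets a report (zero-SNV contigs populate histogram
    bin k = 0). Call sets are expected to be shared-position filtered already.
    """
    index = assembly_index(assembly)
    per_contig: dict = {cid: {} for cid in index}
    for cs in callsets:
        for call in cs.calls:
            if call.contig_id not in per_contig:
                raise IntegrityError(
                    f"call references contig {call.contig_id!r} absent from assembly"
                )
            per_contig[call.contig_id].setdefault(cs.mutant_id, []).append(call)

    reports = []
    for cid, by_mutant in per_contig.items():
        n_mut = len(by_mutant)
        total = sum(len(v) for v in by_mutant.values())
        reports.append(
            ContigReport(
                contig_id=cid,
                per_mutant_snvs=by_mutant,
                n_mutants_mutated=n_mut,
                total_snvs=total,
                is_candidate=n_mut >= config.min_mutants_per_contig,
            )
        )
    reports.sort(key=lambda r: (-r.n_mutants_mutated, -r.total_snvs, r.contig_id))

    counts = {k: 0 for k in range(len(callsets) + 1)}
    for r in reports:
        counts[r.n_mutants_mutated] = counts.get(r.n_mutants_mutated, 0) + 1
    histogram = ContigHistogram(counts, len(index))
    return reports, histogram


def apply_artifact_flags(reports: Iterable[ContigReport], artifact_ids: set) -> None:
    """Mark assembly-artifact contigs in place; a flagged contig is never a candidate."""
    for report in reports:
        if report.contig_id in artifact_ids:
            report.artifact_flag = True
            report.is_candidate = False


def report_candidates(
    reports: Sequence[ContigReport], config: FilterConfig
) -> list[ContigReport]:
    """Candidate contigs (≥ min_mutants_per_contig lines, not artifacts), rank order."""
    return [r for r in reports if r.is_candidate]


# ---------------------------------------------------------------------------
# TSV output


def _mutations_field(report: ContigReport) -> str:
    parts = []
    for mutant_id in sorted(report.per_mutant_snvs):
        muts = ",".join(
            f"{s.position}{s.ref_base}>{s.alt_base}"
            for s in report.per_mutant_snvs[mutant_id]
        )
        parts.append(f"{mutant_id}:{muts}")
    return ";".join(parts)


def write_candidates_tsv(reports: Sequence[ContigReport], path) -> None:
    frame = pd.DataFrame(
        [
            (rank, r.contig_id, r.n_mutants_mutated, r.total_snvs,
             int(r.artifact_flag), _mutations_field(r))
            for rank, r in enumerate(reports, start=1)
        ],
        columns=["rank", "contig", "n_mutants", "total_snvs", "artifact", "mutations"],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_histogram_tsv(histogram: ContigHistogram, path) -> None:
    frame = pd.DataFrame(
        sorted(histogram.counts.items()),
        columns=["n_mutant_lines", "n_contigs"],
    )
    frame.to_csv(path, sep="\t", index=False)
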