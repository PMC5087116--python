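"""Per-mutant calling of near-fixed single-nucleotide variants.

EMS-mutagenised lines are homozygous at induced sites, and flow-sorted
chromosome reads mapped back to the wild-type assembly should therefore show
columns where essentially every read carries the same non-reference base.
The caller emits a variant at a position iff

  (i)   the reference base is uppercase A/C/G/T (repeat-masked and N
        positions are skipped entirely),
  (ii)  the column depth is at least ``min_coverage`` (default 15), and
  (iii) the single most frequent non-reference base has frequency at least
        ``min_allele_frequency`` (default 0.9999, i.e. 99.99 %), where the
        frequency denominator is the number of A/C/G/T-supporting reads at
        the column — deletions and reference skips reflect alignment
        artifacts, not substitutions, and are excluded.

At the default frequency threshold and realistic depths this is equivalent
to demanding that *no* read supports any base other than the alternate.
Ties among non-reference bases yield no call (neither can reach the
threshold). ``callable_bases`` counts every position satisfying (i) and
(ii); it is the denominator for all SNV-density statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .errors import ConfigError, IntegrityError, ValidationError
from .formats_io import PileupColumn, ReferenceContig, assembly_index

_ACGT = "ACGT"
_ACGT_SET = frozenset(_ACGT)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the calling and integration filters.

    min_coverage : reads — columns below this depth are not callable.
    min_allele_frequency : fraction — a near-fixation requirement on the
        alternate allele (0.9999 ⇒ zero dissenting substitution reads at
        depths below 10,000).
    max_mutants_sharing_position : positions carried by more than this many
        independent mutants are discarded as pre-existing variation or
        mapping error (independent EMS hits essentially never coincide).
    min_mutants_per_contig : a contig is reported as a candidate when at
        least this many mutants carry a surviving SNV on it.
    """

    min_coverage: int = 15
    min_allele_frequency: float = 0.9999
    max_mutants_sharing_position: int = 2
    min_mutants_per_contig: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_allele_frequency <= 1):
            raise ConfigError(
                f"min_allele_frequency must be in (0, 1], got {self.min_allele_frequency}"
            )
        if self.min_coverage < 1:
            raise ConfigError(f"min_coverage must be ≥ 1, got {self.min_coverage}")
        if self.max_mutants_sharing_position < 1:
            raise ConfigError("max_mutants_sharing_position must be ≥ 1")
        if self.min_mutants_per_contig < 1:
            raise ConfigError("min_mutants_per_contig must be ≥ 1")


def is_canonical(ref_base: str, alt_base: str) -> bool:
    """True for the canonical EMS transitions G→A and C→T."""
    return (ref_base == "G" and alt_base == "A") or (
        ref_base == "C" and alt_base == "T"
    )


class SnvCall(NamedTuple):
    """One near-fixed substitution in one mutant line (1-based position)."""

    mutant_id: str
    contig_id: str
    position: int
    ref_base: str
    alt_base: str
    alt_frequency: float
    depth: int
    canonical: bool


@dataclass
class MutantCallSet:
    """All surviving calls of one mutant plus its callable-base denominator."""

    mutant_id: str
    calls: list
    callable_bases: int

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def call_mutant_snvs(
    pileup: Iterable[PileupColumn],
    assembly: Union[Sequence[ReferenceContig], Mapping[str, ReferenceContig]],
    config: FilterConfig,
    mutant_id: str,
) -> MutantCallSet:
    """Apply the coverage and allele-frequency filters to one mutant's pileup.

    The pileup must be position-sorted with each contig contiguous; masking
    status is taken from the assembly sequence (lowercase / N skipped).
    """
    index = assembly_index(assembly)
    min_cov = config.min_coverage
    min_af = config.min_allele_frequency

    calls: list = []
    callable_bases = 0
    seq = ""
    seq_len = 0
    cur_contig: Optional[str] = None
    last_pos = 0
    visited: set = set()

    for col in pileup:
        cid = col.contig_id
        pos = col.position
        if cid != cur_contig:
            if cid in visited:
                raise ValidationError(f"pileup not sorted: contig {cid!r} revisited")
            visited.add(cid)
            contig = index.get(cid)
            if contig is None:
                raise IntegrityError(f"pileup contig {cid!r} not in assembly")
            seq = contig.sequence
            seq_len = contig.length
            cur_contig = cid
            last_pos = 0
        elif pos <= last_pos:
            raise ValidationError(
                f"pileup not sorted at {cid}:{pos} (previous position {last_pos})"
            )
        last_pos = pos
        if pos < 1 or pos > seq_len:
            raise IntegrityError(f"position {cid}:{pos} outside contig (length {seq_len})")

        depth = col.depth
        if depth < min_cov:
            continue
        ref = seq[pos - 1]
        if ref not in _ACGT_SET:  # repeat-masked or ambiguous reference
            continue
        callable_bases += 1

        counts = col.counts
        if len(counts) == 1:
            # fast path: unanimous column (the overwhelmingly common case)
            ((base, n),) = counts.items()
            if base == ref or base not in _ACGT_SET:
                continue
            alt, alt_n, total, tied = base, n, n, False
        else:
            a = counts.get("A", 0)
            c = counts.get("C", 0)
            g = counts.get("G", 0)
            t = counts.get("T", 0)
            total = a + c + g + t
            if total == 0:
                continue
            best = [(n, b) for n, b in ((a, "A"), (c, "C"), (g, "G"), (t, "T")) if b != ref]
            best.sort(reverse=True)
            alt_n, alt = best[0]
            tied = alt_n > 0 and best[1][0] == alt_n
        if alt_n == 0 or tied:
            continue
        freq = alt_n / total
        if freq >= min_af:
            calls.append(
                SnvCall(mutant_id, cid, pos, ref, alt, freq, depth, is_canonical(ref, alt))
            )

    calls.sort(key=lambda s: (s.contig_id, s.position))
    return MutantCallSet(mutant_id, calls, callable_bases)


def spectrum(callset: MutantCallSet) -> Optional[float]:
    """Fraction of calls that are canonical EMS transitions; None if no calls."""
    if not callset.calls:
        return None
    return sum(1 for s in callset.calls if s.canonical) / len(callset.calls)


# ---------------------------------------------------------------------------
# TSV round-trip of call sets

_CALL_COLUMNS = [
    "mutant_id",
    "contig",
    "position",
    "ref",
    "alt",
    "frequency",
    "depth",
    "canonical",
]


def write_calls_tsv(callset: MutantCallSet, path) -> None:
    """Write one mutant's calls as TSV; callable_bases rides in a # header."""
    frame = pd.DataFrame(
        [
            (s.mutant_id, s.contig_id, s.position, s.ref_base, s.alt_base,
             s.alt_frequency, s.depth, int(s.canonical))
            for s in callset.calls
        ],
        columns=_CALL_COLUMNS,
    )
    with open(path, "w") as handle:
        handle.write(f"# mutant_id={callset.mutant_id}\tcallable_bases={callset.callable_bases}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_calls_tsv(path) -> MutantCallSet:
    """Inverse of write_calls_tsv."""
    with open(path) as handle:
        header = handle.readline().strip()
        if not header.startswith("# mutant_id="):
            raise ValidationError(f"{path}: missing call-set header line")
        fields = dict(part.split("=", 1) for part in header[2:].split("\t"))
        frame = pd.read_csv(handle, sep="\t")
    calls = [
        SnvCall(
            str(r.mutant_id), str(r.contig), int(r.position), str(r.ref), str(r.alt),
            float(r.frequency), int(r.depth), bool(r.canonical),
        )
        for r in frame.itertuples(index=False)
    ]
    calls.sort(key=lambda s: (s.contig_id, s.position))
    return MutantCallSet(fields["mutant_id"], calls, int(fields["callable_bases"]))
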