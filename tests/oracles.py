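"""Independent brute-force oracles used across the test suite.

These deliberately do not share code with the package: the mpileup oracle
*generates* read-base strings from a chosen event list (so expected counts
are known by construction, never parsed), and the calling/filter oracles
re-derive decisions predicate by predicate.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

ACGT = "ACGT"
DELETION = "*"
OTHER = ">"


def generate_read_bases(rng: np.random.Generator, ref_base: str):
    """Build a random legal mpileup read-base string event by event.

    Returns (string, expected_counts, depth). Expected counts are recorded
    while the string is constructed, making this a construction-side oracle
    for the decoder.
    """
    n_events = int(rng.integers(0, 12))
    parts = []
    expected: Counter = Counter()
    ref = ref_base.upper()
    for _ in range(n_events):
        if rng.random() < 0.2:  # read start marker with mapping quality
            parts.append("^" + chr(int(rng.integers(33, 127))))
        kind = rng.random()
        if kind < 0.5:
            parts.append("." if rng.random() < 0.5 else ",")
            expected[ref if ref in ACGT else OTHER] += 1
        elif kind < 0.8:
            base = ACGT[int(rng.integers(4))]
            parts.append(base if rng.random() < 0.5 else base.lower())
            expected[base] += 1
        elif kind < 0.9:
            parts.append("*")
            expected[DELETION] += 1
        else:
            parts.append(">" if rng.random() < 0.5 else "<")
            expected[OTHER] += 1
        if rng.random() < 0.25:  # indel annotation on the preceding base
            length = int(rng.integers(1, 20))
            seq = "".join(ACGT[int(rng.integers(4))] for _ in range(length))
            sign = "+" if rng.random() < 0.5 else "-"
            parts.append(f"{sign}{length}{seq}")
        if rng.random() < 0.2:  # read end marker
            parts.append("$")
    return "".join(parts), dict(expected), sum(expected.values())


def call_column_oracle(ref_base: str, counts: dict, depth: int, min_coverage: int,
                       min_allele_frequency: float):
    """Literal re-derivation of the three calling predicates for one column.

    Returns (alt, frequency) or None; ``ref_base`` is the assembly base with
    masking information (lowercase / N ⇒ not callable).
    """
    if ref_base not in ACGT:  # predicate (i): unmasked A/C/G/T reference
        return None
    if depth < min_coverage:  # predicate (ii)
        return None
    acgt_counts = {b: counts.get(b, 0) for b in ACGT}
    denominator = sum(acgt_counts.values())
    if denominator == 0:
        return None
    non_ref = {b: n for b, n in acgt_counts.items() if b != ref_base}
    best = max(non_ref.values())
    if best == 0:
        return None
    winners = [b for b, n in non_ref.items() if n == best]
    if len(winners) != 1:  # tie: no single most frequent alternate
        return None
    frequency = best / denominator
    if frequency < min_allele_frequency:  # predicate (iii)
        return None
    return winners[0], frequency


def shared_position_oracle(callsets, max_shared: int):
    """Brute-force shared-position removal by position multiset counting.

    Returns {mutant_id: set of surviving (contig, position)}.
    """
    carriers = defaultdict(set)
    for cs in callsets:
        for call in cs.calls:
            carriers[(call.contig_id, call.position)].add(cs.mutant_id)
    surviving = {}
    for cs in callsets:
        surviving[cs.mutant_id] = {
            (c.contig_id, c.position)
            for c in cs.calls
            if len(carriers[(c.contig_id, c.position)]) <= max_shared
        }
    return surviving
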