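"""False-positive probability model for EMS mutagenesis.

EMS induces almost exclusively G/C→A/T transitions, approximately uniformly
distributed over the genome. Under per-site independence, a mutant with
canonical mutation density d (mutations per callable bp) over callable
sequence of G/C fraction g mutates each G/C site with probability
μ = d / g, so a contig containing n G/C bases carries at least one chance
mutation with probability

    p = 1 − (1 − μ)^n

(the exact complement form; for μ·n ≤ 0.01 this is within 1 % of the linear
approximation μ·n). Across m independent mutant lines the probability that
the *same* contig is hit by chance in every line is the product of the
per-line probabilities — the false-positive probability of a candidate
supported by all m lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


def estimate_mu(n_canonical_snvs: int, callable_gc_bases: int) -> float:
    """Per-G/C-site mutation probability from observed canonical SNV counts."""
    if callable_gc_bases <= 0:
        raise ValueError("callable_gc_bases must be positive")
    if n_canonical_snvs < 0:
        raise ValueError("n_canonical_snvs must be non-negative")
    return n_canonical_snvs / callable_gc_bases


def contig_false_positive_prob(gc_bases_in_contig: int, mu: float) -> float:
    """Probability that a contig with the given G/C content carries ≥1 chance
    mutation in one mutant: 1 − (1 − μ)^n."""
    if not (0.0 <= mu <= 1.0):
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    if gc_bases_in_contig < 0:
        raise ValueError("gc_bases_in_contig must be non-negative")
    if gc_bases_in_contig == 0 or mu == 0.0:
        return 0.0
    if mu == 1.0:
        return 1.0
    # -expm1(n·log1p(-μ)) is 1-(1-μ)^n without cancellation at small μ·n
    return -math.expm1(gc_bases_in_contig * math.log1p(-mu))


def joint_false_positive(per_mutant_probs: Sequence[float]) -> float:
    """Probability the same contig is mutated by chance in every line
    (independence across lines): the product of the per-line probabilities."""
    if len(per_mutant_probs) == 0:
        raise ValueError("need at least one per-mutant probability")
    for p in per_mutant_probs:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability out of [0, 1]: {p}")
    return math.prod(per_mutant_probs)


def format_one_in(p: float) -> str:
    """Render a probability as '1 in X' with X = 1/p at one significant figure.

    X ≥ 10,000 is rendered in scientific style, e.g. '1 in 3 × 10^11'.
    Rounding is half-up on the leading digit.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    x = 1.0 / p
    exponent = math.floor(math.log10(x))
    mantissa = math.floor(x / 10.0**exponent + 0.5)
    if mantissa == 10:
        mantissa = 1
        exponent += 1
    rounded = mantissa * 10**exponent
    if rounded >= 10_000:
        return f"1 in {mantissa} × 10^{exponent}"
    return f"1 in {rounded}"


@dataclass(frozen=True)
class EmsProbabilityModel:
    """Cohort-level chance-hit model.

    d : canonical mutations per callable bp (the mutant's observed density)
    g : fraction of callable bases that are G/C
    n_mutants : number of independent lines in the cohort
    """

    d: float
    g: float
    n_mutants: int

    @property
    def mu(self) -> float:
        """Per-G/C-site mutation probability, d / g."""
        if self.g <= 0:
            raise ValueError("G/C fraction must be positive")
        return self.d / self.g

    @classmethod
    def from_counts(
        cls,
        n_canonical_snvs: int,
        callable_bases: int,
        callable_gc_bases: int,
        n_mutants: int,
    ) -> "EmsProbabilityModel":
        if callable_bases <= 0:
            raise ValueError("callable_bases must be positive")
        return cls(
            d=n_canonical_snvs / callable_bases,
            g=callable_gc_bases / callable_bases,
            n_mutants=n_mutants,
        )

    def per_contig_probability(self, gc_bases_in_contig: int) -> float:
        return contig_false_positive_prob(gc_bases_in_contig, self.mu)

    def joint_probability(self, gc_bases_in_contig: int) -> float:
        p = self.per_contig_probability(gc_bases_in_contig)
        return joint_false_positive([p] * self.n_mutants)
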