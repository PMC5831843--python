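"""Combinatorial library mathematics.

Coupon-collector coverage for a shuffling library of N equiprobable
variants, oversampling guidance, and the shuffling-efficiency statistics
computed from sequenced clone tables.

The coverage model treats each screened clone as an effective uniform draw
with probability ``efficiency`` (clones with a wrong restriction pattern or
a redundant genotype are uninformative loss), so ``n_eff = round(n *
efficiency)`` draws enter the exact inclusion–exclusion formula

    P(all N seen) = sum_{j=0..N} (-1)^j C(N, j) (1 - j/N)^n_eff

evaluated in exact rational arithmetic — no overflow or cancellation even
at N = 128.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence


@dataclass(frozen=True)
class CloneRecord:
    """One sequenced clone: its genotype bitstring, or an invalid pattern."""

    genotype: str
    pattern_ok: bool = True

    def __post_init__(self) -> None:
        if not self.pattern_ok and self.genotype != "invalid":
            raise ValueError('pattern_ok=False requires genotype="invalid"')


@dataclass(frozen=True)
class CoverageQuery:
    """N equiprobable variants, n screened clones, valid-draw efficiency."""

    N: int
    n: int
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must lie in (0, 1]")

    @property
    def n_eff(self) -> int:
        return round(self.n * self.efficiency)


def n_combinations(k: int) -> int:
    """Library size for k independent biallelic mutation sites: 2**k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2**k


def coverage_probability(q: CoverageQuery) -> float:
    """Probability that every one of the N variants appears at least once."""
    N, m = q.N, q.n_eff
    if m < N:
        return 0.0
    total = Fraction(0)
    for j in range(N + 1):
        term = Fraction(comb(N, j)) * Fraction(N - j, N) ** m
        total += term if j % 2 == 0 else -term
    return min(1.0, max(0.0, float(total)))


def expected_distinct(q: CoverageQuery) -> float:
    """Expected number of distinct variants among the effective draws."""
    N, m = q.N, q.n_eff
    return float(N * (1 - Fraction(N - 1, N) ** m))


def clones_for_coverage(N: int, efficiency: float = 1.0, target_p: float = 0.95) -> int:
    """Smallest clone count whose coverage probability reaches ``target_p``.

    Uses bisection on n; coverage_probability is nondecreasing in n.
    """
    if not 0 < target_p < 1:
        raise ValueError("target_p must lie strictly between 0 and 1")

    def p(n: int) -> float:
        return coverage_probability(CoverageQuery(N, n, efficiency))

    hi = max(1, N)
    while p(hi) < target_p:
        hi *= 2
    lo = 0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if p(mid) >= target_p:
            hi = mid
        else:
            lo = mid
    return hi


def shuffling_statistics(
    clones: Sequence[CloneRecord], mode: str = "first_occurrence"
) -> tuple[float, float]:
    """(pct_pattern_ok, pct_nonredundant) for a sequenced clone sample.

    ``pct_nonredundant`` counts, per 100 clones, those carrying a valid
    genotype not seen in any earlier clone (input order): how many clones
    contributed new, non-redundant shuffled sequences.
    ``mode="distinct_over_total"`` instead reports distinct valid genotypes
    over the number of *valid* clones.
    """
    if not clones:
        raise ValueError("need at least one clone")
    n = len(clones)
    n_ok = sum(c.pattern_ok for c in clones)
    seen: set[str] = set()
    first = 0
    for c in clones:
        if c.pattern_ok and c.genotype not in seen:
            seen.add(c.genotype)
            first += 1
    if mode == "first_occurrence":
        pct_nonredundant = 100.0 * first / n
    elif mode == "distinct_over_total":
        pct_nonredundant = 100.0 * len(seen) / n_ok if n_ok else 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * n_ok / n, pct_nonredundant


def oversampling_factor(n: int, N: int) -> float:
    """Screened clones per library variant (e.g. 448/128 = 3.5x)."""
    return n / N


def coverage_report(k: int, n: int, efficiency: float = 1.0) -> dict:
    """JSON-ready summary used by the CLI ``stats`` subcommand."""
    N = n_combinations(k)
    q = CoverageQuery(N, n, efficiency)
    return {
        "k": k,
        "library_size": N,
        "clones": n,
        "efficiency": efficiency,
        "effective_draws": q.n_eff,
        "oversampling_factor": oversampling_factor(n, N),
        "coverage_probability": coverage_probability(q),
        "expected_distinct": expected_distinct(q),
        "clones_for_95pct_coverage": clones_for_coverage(N, efficiency, 0.95),
    }
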