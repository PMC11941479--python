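"""Hypergeometric category over-representation testing.

Given a universe of N miRNAs of which K belong to a category (for example,
primate-specific miRNAs) and a selected set of n miRNAs (for example, those
dysregulated upon DGCR8 loss) containing k category members, the upper-tail
hypergeometric probability P(X >= k) is the exact one-sided enrichment
p-value.  The universe is always supplied by the caller: it should be the
set of miRNAs actually included in the upstream analysis, not all known
miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "EnrichmentInput",
    "hypergeom_enrichment",
    "two_sided_exact_2x2",
    "counts_from_id_lists",
]


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for the 2x2 enrichment contingency.

    N: universe size; K: category size within the universe;
    n: selected-set size; k: overlap of selected set and category.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(
                f"inconsistent counts: need K <= N and n <= N, got {self}"
            )
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"inconsistent counts: need 0 <= k <= min(K, n), got {self}"
            )
        # the selected set cannot contain more non-category members than exist
        if self.n - self.k > self.N - self.K:
            raise ValueError(
                f"inconsistent counts: n - k exceeds N - K, got {self}"
            )


def hypergeom_enrichment(inp: EnrichmentInput) -> float:
    """Exact upper-tail p-value P(X >= k); P(X >= 0) = 1 by construction."""
    if inp.k == 0:
        return 1.0
    # survival function is P(X > k-1) = P(X >= k)
    return float(stats.hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n))


def two_sided_exact_2x2(table) -> float:
    """Two-sided exact test on a 2x2 table (sum of tables with probability
    at most the observed one), as used for the motif depletion comparison."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def counts_from_id_lists(universe: set, category: set, selected: set) -> EnrichmentInput:
    """Derive (N, K, n, k) from ID sets; category/selected are clipped to
    the universe so stray identifiers cannot inflate the counts."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    category = set(category) & universe
    selected = set(selected) & universe
    return EnrichmentInput(
        N=len(universe),
        K=len(category),
        n=len(selected),
        k=len(category & selected),
    )
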