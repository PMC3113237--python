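"""Overlap between genetic and physical domain interactions.

Domain pairs inferred to interact genetically are compared against an
iPfam-style list of domain pairs in physical contact, at two levels:
the participating domains, and the pairs themselves.  Independence of the
two sets is tested with Fisher's exact test (two-sided, point-probability
rule) on the 2x2 membership table over a stated universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Iterable

import numpy as np
from scipy import stats

from .io import canonical_pair

__all__ = ["OverlapReport", "restrict_physical", "fisher_overlap", "compare_overlap"]


@dataclass(frozen=True)
class OverlapReport:
    n_genetic_domains: int
    n_physical_domains: int
    n_shared_domains: int
    n_genetic_pairs: int
    n_physical_pairs: int
    n_shared_pairs: int
    domain_table: tuple[tuple[int, int], tuple[int, int]]
    domain_pvalue: float
    pair_table: tuple[tuple[int, int], tuple[int, int]]
    pair_pvalue: float

    def as_dict(self) -> dict[str, object]:
        return {
            "n_genetic_domains": self.n_genetic_domains,
            "n_physical_domains": self.n_physical_domains,
            "n_shared_domains": self.n_shared_domains,
            "n_genetic_pairs": self.n_genetic_pairs,
            "n_physical_pairs": self.n_physical_pairs,
            "n_shared_pairs": self.n_shared_pairs,
            "domain_table": str(self.domain_table),
            "domain_pvalue": self.domain_pvalue,
            "pair_table": str(self.pair_table),
            "pair_pvalue": self.pair_pvalue,
        }


def restrict_physical(
    physical_pairs: Iterable[tuple[str, str]], domain_universe: Collection[str]
) -> set[tuple[str, str]]:
    """Keep physical pairs whose both domains occur in the studied universe."""
    universe = set(domain_universe)
    return {
        canonical_pair(a, b)
        for a, b in physical_pairs
        if a in universe and b in universe
    }


def fisher_overlap(
    set_a: Collection, set_b: Collection, universe_size: int
) -> tuple[tuple[tuple[int, int], tuple[int, int]], float]:
    """2x2 membership table of two sets over a universe and its Fisher p.

    Table layout: [[|A and B|, |A only|], [|B only|, neither]].  The
    two-sided p-value sums hypergeometric probabilities of all tables (at
    the observed margins) no more likely than the observed one.
    """
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = universe_size - both - only_a - only_b
    if neither < 0:
        raise ValueError(
            f"universe size {universe_size} smaller than |A u B| = "
            f"{both + only_a + only_b}"
        )
    table = ((both, only_a), (only_b, neither))
    p = float(stats.fisher_exact(np.array(table), alternative="two-sided")[1])
    return table, min(p, 1.0)


def compare_overlap(
    genetic_pairs: Iterable[tuple[str, str]],
    physical_pairs: Iterable[tuple[str, str]],
    domain_universe: Collection[str],
    pair_universe_size: int | None = None,
) -> OverlapReport:
    """Full genetic-vs-physical comparison at domain and pair level.

    The domain-level universe is the studied domain universe (all Pfam-A
    accessions in the assignment input).  The pair-level universe defaults
    to all unordered pairs, self pairs included, over the union of domains
    appearing in either list: n(n+1)/2 for n such domains.
    """
    gen = {canonical_pair(a, b) for a, b in genetic_pairs}
    phys = {canonical_pair(a, b) for a, b in physical_pairs}
    gen_domains = {d for p in gen for d in p}
    phys_domains = {d for p in phys for d in p}
    universe = set(domain_universe)
    if not (gen_domains | phys_domains) <= universe:
        raise ValueError("domain universe must contain every listed domain")

    domain_table, domain_p = fisher_overlap(gen_domains, phys_domains, len(universe))

    if pair_universe_size is None:
        n = len(gen_domains | phys_domains)
        pair_universe_size = n * (n + 1) // 2
    pair_table, pair_p = fisher_overlap(gen, phys, pair_universe_size)

    return OverlapReport(
        n_genetic_domains=len(gen_domains),
        n_physical_domains=len(phys_domains),
        n_shared_domains=len(gen_domains & phys_domains),
        n_genetic_pairs=len(gen),
        n_physical_pairs=len(phys),
        n_shared_pairs=len(gen & phys),
        domain_table=domain_table,
        domain_pvalue=domain_p,
        pair_table=pair_table,
        pair_pvalue=pair_p,
    )
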