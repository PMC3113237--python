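"""Evidence scores and significance selection for fitted domain pairs.

The evidence score of a domain pair is a positives-only log-ratio: over the
SLGIs containing the pair, it sums the log of the modeled interaction
probability against the probability recomputed with that pair's theta set
to 0 (all other thetas held fixed — a plug-in ratio, not a refit, and not a
standard likelihood-ratio test).  A score of 2 therefore means excluding
the pair drops the modeled probability of its SLGIs by a factor of
e^2 ~ 7.4 overall.

Pairs that are the *sole* candidate explaining an SLGI would get an
infinite score; the exclusion probability is floored (default 1e-8) so
they get a large finite score instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .em import PairKey, contained_pairs, protein_pair_probability
from .io import DomainAssignment, InteractionCatalog, canonical_pair

__all__ = [
    "DomainPairStats",
    "evidence_score",
    "evidence_scores",
    "annotate_counts",
    "select_significant",
    "build_pair_stats",
]

DEFAULT_FLOOR = 1e-8


@dataclass(frozen=True)
class DomainPairStats:
    """One row of the reportable per-pair statistics table."""

    key: PairKey
    theta: float
    escore: float
    m0: int = 0
    n_proteins_i: int = 0
    n_proteins_j: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.escore):
            raise ValueError("evidence score must be finite (apply the floor)")


def _excluded_probability(p_full: float, theta_ij: float) -> float:
    """Noisy-OR probability with one factor removed, from the full value."""
    # 1 - P_full = (1 - theta_ij) * prod_others  =>  divide the factor out
    return -math.expm1(math.log1p(-p_full) - math.log1p(-theta_ij))


def evidence_score(
    pair: PairKey,
    theta: Mapping[PairKey, float],
    catalog: InteractionCatalog,
    assignments: DomainAssignment,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Evidence score of one pair: sum over its SLGIs of ln(P_full/P_excl).

    The exclusion probability is floored at ``floor``; a pair contained in
    no SLGI scores 0 (empty sum).
    """
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must lie in (0, 1)")
    key = canonical_pair(*pair)
    if key not in theta:
        raise KeyError(f"pair {key} has no fitted probability")
    t = theta[key]
    total = 0.0
    for m, n in catalog:
        pairs_mn = contained_pairs(
            assignments.domains_of(m), assignments.domains_of(n)
        )
        if key not in pairs_mn:
            continue
        p_full = protein_pair_probability(theta, assignments.domains_of(m),
                                          assignments.domains_of(n))
        p_excl = max(_excluded_probability(p_full, t), floor)
        total += math.log(p_full / p_excl)
    return total


def evidence_scores(
    theta: Mapping[PairKey, float],
    catalog: InteractionCatalog,
    assignments: DomainAssignment,
    floor: float = DEFAULT_FLOOR,
) -> dict[PairKey, float]:
    """Evidence scores for every fitted pair in one sweep over the catalog."""
    if not 0.0 < floor < 1.0:
        raise ValueError("floor must lie in (0, 1)")
    scores = {key: 0.0 for key in theta}
    for m, n in catalog:
        dom_m = assignments.domains_of(m)
        dom_n = assignments.domains_of(n)
        p_full = protein_pair_probability(theta, dom_m, dom_n)
        for key in contained_pairs(dom_m, dom_n):
            t = theta.get(key)
            if t is None:
                continue
            p_excl = max(_excluded_probability(p_full, t), floor)
            scores[key] += math.log(p_full / p_excl)
    return scores


def annotate_counts(
    stats: Iterable[DomainPairStats],
    assignments: DomainAssignment,
    catalog: InteractionCatalog,
) -> list[DomainPairStats]:
    """Fill per-domain protein counts and SLGI occurrence counts.

    ``n_proteins_x`` counts proteins whose domain set contains x; ``m0``
    counts SLGIs containing the pair.  Domains absent everywhere count 0.
    """
    proteins_with = assignments.proteins_with_domain()
    m0_counts: dict[PairKey, int] = {}
    for m, n in catalog:
        for key in contained_pairs(
            assignments.domains_of(m), assignments.domains_of(n)
        ):
            m0_counts[key] = m0_counts.get(key, 0) + 1
    return [
        DomainPairStats(
            key=s.key,
            theta=s.theta,
            escore=s.escore,
            m0=m0_counts.get(s.key, 0),
            n_proteins_i=len(proteins_with.get(s.key[0], ())),
            n_proteins_j=len(proteins_with.get(s.key[1], ())),
        )
        for s in stats
    ]


def build_pair_stats(
    theta: Mapping[PairKey, float],
    catalog: InteractionCatalog,
    assignments: DomainAssignment,
    floor: float = DEFAULT_FLOOR,
) -> list[DomainPairStats]:
    """Full stats table: probabilities, evidence scores and counts."""
    scores = evidence_scores(theta, catalog, assignments, floor=floor)
    bare = [
        DomainPairStats(key=key, theta=theta[key], escore=scores[key])
        for key in sorted(theta)
    ]
    return annotate_counts(bare, assignments, catalog)


def select_significant(
    stats: Iterable[DomainPairStats],
    e_min: float = 2.0,
    p_min: float = 0.5,
) -> list[DomainPairStats]:
    """Significant pairs: evidence score >= e_min OR probability > p_min.

    The evidence cut is inclusive, the probability cut strict; output is
    sorted by evidence score descending.
    """
    kept = [s for s in stats if s.escore >= e_min or s.theta > p_min]
    return sorted(kept, key=lambda s: (-s.escore, s.key))
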