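"""Genome-scale SLGI prediction under the fitted noisy-OR model.

Every unordered protein pair in a chosen universe is scored with the
noisy-OR probability implied by the fitted domain-pair thetas; pairs whose
probability exceeds a threshold are emitted, flagged novel when absent
from the training catalog.  Scoring streams pair by pair so a universe of
P proteins (P(P-1)/2 evaluations) never has to be materialized at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from .em import PairKey, protein_pair_probability
from .io import DomainAssignment, InteractionCatalog, canonical_pair

__all__ = [
    "PredictionRecord",
    "iter_predictions",
    "predict_all",
    "count_by_threshold",
]


@dataclass(frozen=True)
class PredictionRecord:
    """A scored protein pair; members are canonically ordered."""

    protein_a: str
    protein_b: str
    probability: float
    is_novel: bool

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            raise ValueError("record members must be canonically ordered")
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("emitted records must have probability in (0, 1]")


def iter_predictions(
    theta: Mapping[PairKey, float],
    assignments: DomainAssignment,
    protein_universe: Iterable[str] | None = None,
    threshold: float = 0.0,
    catalog: InteractionCatalog | None = None,
) -> Iterator[PredictionRecord]:
    """Lazily score all unordered protein pairs, yielding those above threshold.

    ``threshold=0`` keeps exactly the pairs with strictly positive modeled
    probability.  Universe proteins must all carry domains.
    """
    proteins = sorted(protein_universe) if protein_universe is not None else sorted(
        assignments.proteins
    )
    missing = [p for p in proteins if p not in assignments]
    if missing:
        raise ValueError(f"universe proteins lack domains: {missing[:5]}")
    known = catalog.pairs if catalog is not None else frozenset()
    dom = [assignments.domains_of(p) for p in proteins]
    for ia in range(len(proteins)):
        for ib in range(ia + 1, len(proteins)):
            p = protein_pair_probability(theta, dom[ia], dom[ib])
            if p > threshold:
                pair = (proteins[ia], proteins[ib])
                yield PredictionRecord(
                    protein_a=pair[0],
                    protein_b=pair[1],
                    probability=p,
                    is_novel=pair not in known,
                )


def predict_all(
    theta: Mapping[PairKey, float],
    assignments: DomainAssignment,
    protein_universe: Iterable[str] | None = None,
    threshold: float = 0.0,
    catalog: InteractionCatalog | None = None,
) -> list[PredictionRecord]:
    """Materialized predictions sorted by probability descending.

    Convenience wrapper over :func:`iter_predictions`; for very large
    universes, stream the iterator to disk instead.
    """
    records = list(
        iter_predictions(theta, assignments, protein_universe, threshold, catalog)
    )
    records.sort(key=lambda r: (-r.probability, r.protein_a, r.protein_b))
    return records


def count_by_threshold(
    records: Iterable[PredictionRecord],
    thresholds: Sequence[float],
) -> dict[float, int]:
    """Number of records with probability strictly above each threshold.

    Thresholds must arrive sorted ascending; counts are non-increasing.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    counts = dict.fromkeys(thresholds, 0)
    for rec in records:
        for t in thresholds:
            if rec.probability > t:
                counts[t] += 1
            else:
                break  # ascending thresholds: no later one can pass
    return counts
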