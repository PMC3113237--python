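"""EM estimation of domain-domain genetic interaction probabilities.

The generative model is a noisy-OR: two proteins m and n are synthetic
lethal (P_mn = 1) if and only if at least one unordered domain pair (i, j)
with i in one protein and j in the other genetically interacts (D_ij = 1),
the D_ij being independent Bernoulli(theta_ij) events.  Hence

    Pr(P_mn = 1) = 1 - prod_{(i,j) in pairs(m,n)} (1 - theta_ij),

where pairs(m, n) is the set of *distinct* unordered domain pairs between
the two proteins' domain sets (a pair realizable in both orientations still
contributes a single Bernoulli event: D_ij is a property of the domain pair,
not of a placement).

Only *candidate* pairs — domain pairs occurring in at least one observed
SLGI — receive a fitted theta; all other pairs are fixed at 0.  For each
candidate we keep two counts:

* ``M0``: the number of SLGIs containing the pair, and
* ``K``: the number of non-SLGI protein pairs (over a configurable protein
  universe) containing the pair; K is fixed for the whole EM run.

The objective maximized is the penalized (MAP) log-likelihood

    L = sum_{SLGI (m,n)} ln Pr(P_mn = 1)
      + sum_{pairs} K_ij ln(1 - theta_ij)
      + sum_{pairs} [a ln theta_ij + b ln(1 - theta_ij)],

with Beta-style pseudocounts a = b = 1 by default.  The E-step distributes
each positive observation over its contained pairs,

    E[M_ij] = sum_{SLGI (m,n) containing (i,j)} theta_ij / P_mn,
    E[N_ij] = sum_{SLGI (m,n) containing (i,j)} (1 - theta_ij / P_mn),

(the posterior probability that D_ij caused the observed lethality), and
the M-step sets theta_ij = (E[M] + a) / (E[M] + E[N] + K + a + b).  Because
the M-step exactly maximizes the expected complete-data objective, L is
non-decreasing along the iteration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import DomainAssignment, InteractionCatalog, canonical_pair

__all__ = [
    "PairCounts",
    "EMConfig",
    "EMResult",
    "contained_pairs",
    "enumerate_candidate_pairs",
    "count_k",
    "attach_k_counts",
    "protein_pair_probability",
    "penalized_loglik",
    "em_fit",
]

logger = logging.getLogger(__name__)

PairKey = tuple[str, str]

#: clamp bound applied before any log evaluation; with a = b >= 1 the EM
#: update can never reach it in exact arithmetic.
THETA_CLAMP = 1e-12


@dataclass
class PairCounts:
    """Occurrence counts for one candidate domain pair."""

    m0: int
    k: int = 0

    def __post_init__(self) -> None:
        if self.m0 < 0 or self.k < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EMConfig:
    """Tuning knobs for the EM run.

    a, b
        Pseudocounts guarding Pr(D=1) and Pr(D=0) against zero when a
        domain pair is rare; both default to 1.
    tol
        Convergence threshold on the absolute change of the penalized
        log-likelihood between iterations.
    max_iter
        Iteration cap; exceeding it returns ``converged=False``.
    protein_universe
        Proteins over which the negative count K is taken; ``None`` means
        every protein in the assignment table.
    """

    a: float = 1.0
    b: float = 1.0
    tol: float = 1e-6
    max_iter: int = 500
    protein_universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("pseudocounts must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter <= 0:
            raise ValueError("max_iter must be > 0")


@dataclass
class EMResult:
    """Converged estimates plus the diagnostic trail of the run."""

    theta: dict[PairKey, float]
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    counts: dict[PairKey, PairCounts] = field(default_factory=dict)


def contained_pairs(dom_m: Iterable[str], dom_n: Iterable[str]) -> set[PairKey]:
    """Distinct unordered domain pairs between two proteins' domain sets."""
    return {canonical_pair(i, j) for i in dom_m for j in dom_n}


def enumerate_candidate_pairs(
    catalog: InteractionCatalog, assignments: DomainAssignment
) -> dict[PairKey, PairCounts]:
    """Candidate domain pairs and their SLGI occurrence counts M0.

    A pair is counted once per SLGI no matter how many orientations
    realize it within that SLGI.
    """
    counts: dict[PairKey, PairCounts] = {}
    for m, n in catalog:
        for key in contained_pairs(assignments.domains_of(m), assignments.domains_of(n)):
            if key in counts:
                counts[key].m0 += 1
            else:
                counts[key] = PairCounts(m0=1)
    return counts


def _n_realizing_pairs(
    i: str, j: str, proteins_with: Mapping[str, set[str]]
) -> int:
    """Unordered distinct protein pairs whose domain sets realize (i, j)."""
    set_i = proteins_with.get(i, set())
    if i == j:
        n = len(set_i)
        return n * (n - 1) // 2
    set_j = proteins_with.get(j, set())
    both = len(set_i & set_j)
    only_i = len(set_i) - both
    only_j = len(set_j) - both
    return only_i * only_j + both * (only_i + only_j) + both * (both - 1) // 2


def count_k(
    pair: PairKey,
    assignments: DomainAssignment,
    protein_universe: Iterable[str],
    catalog: InteractionCatalog,
) -> int:
    """Number of non-SLGI protein pairs in the universe containing ``pair``.

    Counts unordered pairs (m, n), m != n, of universe proteins with domain
    i in one protein and j in the other, then removes those present in the
    catalog.  Each protein pair counts once regardless of orientation.
    """
    i, j = canonical_pair(*pair)
    universe = set(protein_universe)
    if not universe >= catalog.proteins:
        raise ValueError("protein universe must contain all catalog proteins")
    proteins_with: dict[str, set[str]] = {}
    for p in universe:
        if p in assignments:
            for d in assignments.domains_of(p):
                if d == i or d == j:
                    proteins_with.setdefault(d, set()).add(p)
    total = _n_realizing_pairs(i, j, proteins_with)
    in_catalog = sum(
        1
        for m, n in catalog
        if (i, j)
        in contained_pairs(assignments.domains_of(m), assignments.domains_of(n))
    )
    return total - in_catalog


def attach_k_counts(
    candidates: dict[PairKey, PairCounts],
    assignments: DomainAssignment,
    protein_universe: Iterable[str],
    catalog: InteractionCatalog,
) -> dict[PairKey, PairCounts]:
    """Fill ``k`` for every candidate in one pass (bulk form of count_k).

    Because every candidate occurs in >= 1 SLGI and the universe contains
    all catalog proteins, the catalog pairs realizing a candidate are
    exactly its M0 SLGIs.
    """
    universe = set(protein_universe)
    if not universe >= catalog.proteins:
        raise ValueError("protein universe must contain all catalog proteins")
    proteins_with: dict[str, set[str]] = {}
    for p in universe:
        if p in assignments:
            for d in assignments.domains_of(p):
                proteins_with.setdefault(d, set()).add(p)
    for (i, j), c in candidates.items():
        c.k = _n_realizing_pairs(i, j, proteins_with) - c.m0
        if c.k < 0:
            raise AssertionError(
                f"negative K for pair ({i},{j}); universe inconsistent with catalog"
            )
    return candidates


def protein_pair_probability(
    theta: Mapping[PairKey, float],
    dom_m: Iterable[str],
    dom_n: Iterable[str],
) -> float:
    """Noisy-OR probability that proteins with these domain sets interact.

    Domain pairs absent from ``theta`` contribute a factor of 1 (theta 0).
    """
    log_miss = 0.0
    for key in contained_pairs(dom_m, dom_n):
        t = theta.get(key, 0.0)
        if t > 0.0:
            log_miss += math.log1p(-t)
    return -math.expm1(log_miss)


def penalized_loglik(
    theta: Mapping[PairKey, float],
    candidates: Mapping[PairKey, PairCounts],
    catalog: InteractionCatalog,
    assignments: DomainAssignment,
    config: EMConfig,
) -> float:
    """Penalized log-likelihood of the catalog under ``theta``.

    Raises a domain error when a pseudocount is positive but its theta sits
    on the boundary {0, 1}, where the penalty is -inf.
    """
    total = 0.0
    for key, c in candidates.items():
        t = theta[key]
        if (config.a > 0 and t <= 0.0) or (config.b > 0 and t >= 1.0):
            raise ValueError(
                f"theta[{key}] = {t} lies on the boundary; penalized "
                "log-likelihood undefined with positive pseudocounts"
            )
        log1m = math.log1p(-t) if t < 1.0 else -math.inf
        logt = math.log(t) if t > 0.0 else -math.inf
        total += c.k * log1m + config.a * logt + config.b * log1m
    for m, n in catalog:
        p = protein_pair_probability(
            theta, assignments.domains_of(m), assignments.domains_of(n)
        )
        total += math.log(p)
    return total


def _index_catalog(
    catalog: InteractionCatalog,
    assignments: DomainAssignment,
    keys: Sequence[PairKey],
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten per-SLGI candidate-pair membership into index arrays.

    Returns ``flat`` (concatenated candidate indices over SLGIs, each SLGI's
    block sorted) and ``sizes`` (block length per SLGI).
    """
    index = {key: pos for pos, key in enumerate(keys)}
    flat: list[int] = []
    sizes: list[int] = []
    for m, n in catalog:
        block = sorted(
            index[key]
            for key in contained_pairs(
                assignments.domains_of(m), assignments.domains_of(n)
            )
        )
        flat.extend(block)
        sizes.append(len(block))
    return np.asarray(flat, dtype=np.int64), np.asarray(sizes, dtype=np.int64)


def em_fit(
    catalog: InteractionCatalog,
    assignments: DomainAssignment,
    config: EMConfig | None = None,
) -> EMResult:
    """Fit theta for every candidate domain pair by MAP-EM.

    Initialization sets M to the SLGI occurrence count and N to 0, giving
    theta0 = (M0 + a) / (M0 + K + a + b); iteration stops when the change
    in penalized log-likelihood drops below ``config.tol``.
    """
    config = config or EMConfig()
    if len(catalog) == 0:
        raise ValueError("catalog is empty; nothing to fit")
    missing = catalog.proteins - assignments.proteins
    if missing:
        raise ValueError(f"catalog proteins lack domain assignments: {sorted(missing)[:5]}")

    universe = (
        set(config.protein_universe)
        if config.protein_universe is not None
        else assignments.proteins
    )
    candidates = enumerate_candidate_pairs(catalog, assignments)
    attach_k_counts(candidates, assignments, universe, catalog)

    keys: list[PairKey] = sorted(candidates)
    m0 = np.asarray([candidates[k].m0 for k in keys], dtype=np.float64)
    kneg = np.asarray([candidates[k].k for k in keys], dtype=np.float64)
    flat, sizes = _index_catalog(catalog, assignments, keys)
    offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    repeat = np.repeat(np.arange(len(sizes)), sizes)

    a, b = config.a, config.b
    denom = m0 + kneg + a + b
    theta = (m0 + a) / denom
    theta = np.clip(theta, THETA_CLAMP, 1.0 - THETA_CLAMP)

    def loglik(th: np.ndarray) -> float:
        log1m = np.log1p(-th)
        per_slgi = np.add.reduceat(log1m[flat], offsets)
        p_slgi = -np.expm1(per_slgi)
        return float(
            np.sum(np.log(p_slgi))
            + np.sum(kneg * log1m)
            + np.sum(a * np.log(th) + b * log1m)
        )

    trace = [loglik(theta)]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        log1m = np.log1p(-theta)
        per_slgi = np.add.reduceat(log1m[flat], offsets)
        p_slgi = -np.expm1(per_slgi)
        # E-step: posterior responsibility of each pair for each positive
        e_m = np.bincount(
            flat, weights=theta[flat] / p_slgi[repeat], minlength=len(keys)
        )
        # E[M] + E[N] telescopes to M0, so the M-step denominator is fixed
        theta_new = np.clip((e_m + a) / denom, THETA_CLAMP, 1.0 - THETA_CLAMP)
        ll = loglik(theta_new)
        delta = ll - trace[-1]
        max_step = float(np.max(np.abs(theta_new - theta)))
        logger.debug(
            "EM iter %d: loglik=%.10g dloglik=%.3g max|dtheta|=%.3g",
            n_iter, ll, delta, max_step,
        )
        theta = theta_new
        trace.append(ll)
        if abs(delta) < config.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM did not converge within %d iterations (last |dL|=%.3g)",
            config.max_iter, abs(trace[-1] - trace[-2]),
        )
    return EMResult(
        theta={key: float(t) for key, t in zip(keys, theta)},
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        counts=candidates,
    )
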