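"""Synthetic worlds for end-to-end testing and benchmarking.

A world is generated forward from the same noisy-OR model the estimator
inverts: proteins receive small Pfam-like domain sets, a handful of domain
pairs are planted as true genetic interactions with known probabilities,
and every unordered protein pair enters the SLGI catalog with probability
1 - (1 - background) * prod(1 - theta*_ij) over its planted pairs.  The
background term is a per-protein-pair false-positive rate — equivalent to
one extra always-contained pseudo domain pair — so the generative law
stays exactly noisy-OR plus label noise.

Default sizes (60 domains, 250 proteins, 1-3 domains per protein, 12
planted pairs with theta* in [0.7, 0.95], background 0.01) give a catalog
of a few hundred SLGIs: large enough that planted pairs are well
identified, small enough to fit in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .em import EMResult, PairKey, contained_pairs
from .io import DomainAssignment, InteractionCatalog, canonical_pair

__all__ = ["WorldParams", "SyntheticWorld", "generate_world", "recovery_metrics",
           "write_world"]


@dataclass(frozen=True)
class WorldParams:
    """Generation parameters; defaults define the standard benchmark world."""

    n_domains: int = 60
    n_proteins: int = 250
    domains_per_protein: tuple[int, int] = (1, 3)  # inclusive uniform range
    n_planted_pairs: int = 12
    theta_range: tuple[float, float] = (0.7, 0.95)
    background: float = 0.01

    def __post_init__(self) -> None:
        if self.n_domains < 2 or self.n_proteins < 2:
            raise ValueError("need >= 2 domains and >= 2 proteins")
        lo, hi = self.domains_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("invalid domains-per-protein range")
        tlo, thi = self.theta_range
        if not 0.0 < tlo <= thi <= 1.0:
            raise ValueError("planted theta values must lie in (0, 1]")
        if not 0.0 <= self.background < 1.0:
            raise ValueError("background must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticWorld:
    assignments: DomainAssignment
    theta_true: dict[PairKey, float]
    catalog: InteractionCatalog
    seed: int
    params: WorldParams


def generate_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Sample a reproducible world: same seed, bit-identical output.

    Planted pairs are drawn uniformly without replacement from the domain
    pairs actually realizable by some protein pair; raises if none exist
    or fewer than requested.
    """
    params = params or WorldParams()
    rng = np.random.default_rng(seed)

    domains = [f"D{i:04d}" for i in range(params.n_domains)]
    proteins = [f"P{i:04d}" for i in range(params.n_proteins)]
    lo, hi = params.domains_per_protein
    sizes = rng.integers(lo, hi + 1, size=params.n_proteins)
    mapping = {
        p: frozenset(domains[k] for k in rng.choice(params.n_domains, size=int(s),
                                                    replace=False))
        for p, s in zip(proteins, sizes)
    }
    assignments = DomainAssignment(mapping)

    dom_sets = [mapping[p] for p in proteins]
    realizable: set[PairKey] = set()
    pair_keys: list[list[PairKey]] = []  # per protein pair, its contained pairs
    index_pairs: list[tuple[int, int]] = []
    for ia in range(len(proteins)):
        for ib in range(ia + 1, len(proteins)):
            keys = sorted(contained_pairs(dom_sets[ia], dom_sets[ib]))
            realizable.update(keys)
            pair_keys.append(keys)
            index_pairs.append((ia, ib))
    if not realizable:
        raise ValueError("no realizable domain pairs; world cannot be planted")
    realizable_sorted = sorted(realizable)
    if params.n_planted_pairs > len(realizable_sorted):
        raise ValueError(
            f"cannot plant {params.n_planted_pairs} pairs; only "
            f"{len(realizable_sorted)} realizable"
        )
    chosen = rng.choice(len(realizable_sorted), size=params.n_planted_pairs,
                        replace=False)
    tlo, thi = params.theta_range
    theta_true = {
        realizable_sorted[int(c)]: float(rng.uniform(tlo, thi))
        for c in sorted(chosen)
    }

    log_bg = np.log1p(-params.background)
    slgi: set[tuple[str, str]] = set()
    unif = rng.random(len(index_pairs))
    for pos, ((ia, ib), keys) in enumerate(zip(index_pairs, pair_keys)):
        log_miss = log_bg
        certain = False
        for key in keys:
            t = theta_true.get(key)
            if t is not None:
                if t >= 1.0:
                    certain = True
                    break
                log_miss += np.log1p(-t)
        p = 1.0 if certain else -np.expm1(log_miss)
        if unif[pos] < p:
            slgi.add(canonical_pair(proteins[ia], proteins[ib]))
    return SyntheticWorld(
        assignments=assignments,
        theta_true=theta_true,
        catalog=InteractionCatalog(frozenset(slgi)),
        seed=seed,
        params=params,
    )


def recovery_metrics(world: SyntheticWorld, result: EMResult) -> tuple[float, float]:
    """How well the fit recovered the planted structure.

    Returns ``(ranking_score, mean_abs_error)``: the probability that a
    random (planted, non-planted) candidate pair is ordered correctly by
    fitted theta (ties count 1/2) and the mean absolute theta error over
    planted pairs that appear among the candidates.
    """
    planted = [k for k in result.theta if k in world.theta_true]
    others = [k for k in result.theta if k not in world.theta_true]
    if not planted:
        raise ValueError("no planted pair appears among the fitted candidates")
    err = float(
        np.mean([abs(result.theta[k] - world.theta_true[k]) for k in planted])
    )
    if not others:
        return 1.0, err
    tp = np.array([result.theta[k] for k in planted])
    tn = np.array([result.theta[k] for k in others])
    wins = (tp[:, None] > tn[None, :]).sum() + 0.5 * (tp[:, None] == tn[None, :]).sum()
    return float(wins / (len(tp) * len(tn))), err


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write assignments, interactions and ground truth as standard TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": outdir / "assignments.tsv",
        "interactions": outdir / "interactions.tsv",
        "theta_true": outdir / "theta_true.tsv",
    }
    with paths["assignments"].open("w", encoding="utf-8") as fh:
        fh.write("# protein\tdomain\n")
        for p in sorted(world.assignments.proteins):
            for d in sorted(world.assignments.domains_of(p)):
                fh.write(f"{p}\t{d}\n")
    with paths["interactions"].open("w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in world.catalog:
            fh.write(f"{a}\t{b}\n")
    with paths["theta_true"].open("w", encoding="utf-8") as fh:
        fh.write("# domain_a\tdomain_b\ttheta_true\n")
        for (a, b), t in sorted(world.theta_true.items()):
            fh.write(f"{a}\t{b}\t{t:.6g}\n")
    return paths
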