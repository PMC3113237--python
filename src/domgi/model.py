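"""Model/Results facade over the estimation pipeline.

:class:`DomainInteractionModel` holds the cleaned data and the EM
configuration; :meth:`~DomainInteractionModel.fit` runs the EM and returns
a :class:`DomainInteractionResults` carrying the fitted probabilities, the
likelihood trace, evidence scores, significance selection, prediction and
a printable summary — the usual fit-then-inspect workflow of statistical
modelling packages.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx

from . import io
from .em import EMConfig, EMResult, PairKey, em_fit
from .evidence import (
    DEFAULT_FLOOR,
    DomainPairStats,
    build_pair_stats,
    select_significant,
)
from .io import DomainAssignment, FilterReport, InteractionCatalog
from .network import NetworkSummary, build_network, summarize
from .predict import PredictionRecord, iter_predictions, predict_all

__all__ = ["DomainInteractionModel", "DomainInteractionResults"]


class DomainInteractionModel:
    """Noisy-OR model of SLGIs driven by latent domain-pair interactions.

    Parameters
    ----------
    catalog
        Deduplicated, domain-filtered SLGI protein pairs.
    assignments
        Protein -> domain-set mapping covering every catalog protein.
    a, b, tol, max_iter, protein_universe
        EM configuration; see :class:`~domgi.em.EMConfig`.
    """

    def __init__(
        self,
        catalog: InteractionCatalog,
        assignments: DomainAssignment,
        a: float = 1.0,
        b: float = 1.0,
        tol: float = 1e-6,
        max_iter: int = 500,
        protein_universe: Iterable[str] | None = None,
    ) -> None:
        self.catalog = catalog
        self.assignments = assignments
        self.config = EMConfig(
            a=a,
            b=b,
            tol=tol,
            max_iter=max_iter,
            protein_universe=(
                frozenset(protein_universe) if protein_universe is not None else None
            ),
        )
        self.filter_report: FilterReport | None = None

    @classmethod
    def from_files(
        cls, assignments_path, interactions_path, **config
    ) -> "DomainInteractionModel":
        """Build a model from assignment and interaction TSVs.

        Raw pairs are deduplicated and domain-filtered; the stage counts
        are kept on ``model.filter_report``.
        """
        assignments = io.read_domain_assignments(assignments_path)
        raw = io.read_interactions(interactions_path)
        catalog, report = io.filter_catalog(raw, assignments)
        model = cls(catalog, assignments, **config)
        model.filter_report = report
        return model

    def fit(self) -> "DomainInteractionResults":
        """Run the EM to convergence and wrap the estimates."""
        result = em_fit(self.catalog, self.assignments, self.config)
        return DomainInteractionResults(self, result)


class DomainInteractionResults:
    """Fitted domain-pair probabilities plus everything derived from them."""

    def __init__(self, model: DomainInteractionModel, em_result: EMResult) -> None:
        self.model = model
        self.em_result = em_result
        self._stats_cache: dict[float, list[DomainPairStats]] = {}

    # -- estimates -----------------------------------------------------
    @property
    def theta(self) -> dict[PairKey, float]:
        return self.em_result.theta

    @property
    def loglik_trace(self) -> list[float]:
        return self.em_result.loglik_trace

    @property
    def converged(self) -> bool:
        return self.em_result.converged

    @property
    def n_iter(self) -> int:
        return self.em_result.n_iter

    # -- evidence ------------------------------------------------------
    def pair_stats(self, floor: float = DEFAULT_FLOOR) -> list[DomainPairStats]:
        """Per-pair probability, evidence score and occurrence counts."""
        if floor not in self._stats_cache:
            self._stats_cache[floor] = build_pair_stats(
                self.theta, self.model.catalog, self.model.assignments, floor=floor
            )
        return self._stats_cache[floor]

    def significant(
        self,
        e_min: float = 2.0,
        p_min: float = 0.5,
        floor: float = DEFAULT_FLOOR,
    ) -> list[DomainPairStats]:
        """Pairs with evidence >= e_min or probability > p_min."""
        return select_significant(self.pair_stats(floor), e_min=e_min, p_min=p_min)

    # -- prediction ----------------------------------------------------
    def predict(
        self,
        protein_universe: Iterable[str] | None = None,
        threshold: float = 0.0,
    ) -> list[PredictionRecord]:
        """Score all unordered protein pairs; see :func:`domgi.predict.predict_all`."""
        return predict_all(
            self.theta,
            self.model.assignments,
            protein_universe=protein_universe,
            threshold=threshold,
            catalog=self.model.catalog,
        )

    def iter_predict(
        self,
        protein_universe: Iterable[str] | None = None,
        threshold: float = 0.0,
    ):
        return iter_predictions(
            self.theta,
            self.model.assignments,
            protein_universe=protein_universe,
            threshold=threshold,
            catalog=self.model.catalog,
        )

    # -- network -------------------------------------------------------
    def network(self, e_min: float = 2.0, p_min: float = 0.5) -> nx.Graph:
        """Domain graph over the significant pairs."""
        return build_network(s.key for s in self.significant(e_min, p_min))

    def network_summary(self, e_min: float = 2.0, p_min: float = 0.5) -> NetworkSummary:
        return summarize(self.network(e_min, p_min))

    # -- reporting -----------------------------------------------------
    def summary(self, top: int = 10) -> str:
        """Printable digest: fit diagnostics and the top-evidence pairs."""
        lines = [
            "Domain genetic interaction model (noisy-OR, MAP-EM)",
            f"  SLGIs fitted:        {len(self.model.catalog)}",
            f"  candidate pairs:     {len(self.theta)}",
            f"  iterations:          {self.n_iter} "
            f"({'converged' if self.converged else 'NOT converged'})",
            f"  penalized loglik:    {self.loglik_trace[-1]:.4f}",
            "",
            f"Top {top} domain pairs by evidence score:",
            f"  {'E score':>9} {'Prob.':>7} {'domain_a':<10} {'domain_b':<10} "
            f"{'#prot_a':>7} {'#prot_b':>7} {'#GI':>5}",
        ]
        ranked = sorted(self.pair_stats(), key=lambda s: (-s.escore, s.key))
        for s in ranked[:top]:
            lines.append(
                f"  {s.escore:>9.2f} {s.theta:>7.3f} {s.key[0]:<10} {s.key[1]:<10} "
                f"{s.n_proteins_i:>7} {s.n_proteins_j:>7} {s.m0:>5}"
            )
        return "\n".join(lines)
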