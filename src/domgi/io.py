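"""Reading, validation and writing of the flat-file tables the pipeline uses.

Three kinds of input arrive as tab-separated text in the style of SGD/Pfam
flat files (``#`` comments, extra columns ignored):

* protein -> Pfam-A domain assignments (one row per assignment),
* synthetic-lethal genetic interaction (SLGI) protein pairs,
* domain physical-interaction pairs (iPfam-style).

Pairs of proteins or domains are symmetric relations throughout, so every
pair is stored canonically as ``(min, max)`` under lexicographic ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .evidence import DomainPairStats

__all__ = [
    "DomainAssignment",
    "InteractionCatalog",
    "FilterReport",
    "canonical_pair",
    "read_domain_assignments",
    "read_interactions",
    "read_domain_pairs",
    "filter_catalog",
    "write_domain_pair_table",
    "read_domain_pair_table",
    "write_predictions",
    "write_theta_table",
    "read_theta_table",
    "write_report",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` in canonical (sorted) order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DomainAssignment:
    """Set-semantics mapping from protein identifier to its Pfam-A domains.

    Repeated domains within one protein count once: domain content is
    presence/absence, matching how proteins-per-domain tallies are made.
    """

    protein_to_domains: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for protein, doms in self.protein_to_domains.items():
            if not doms:
                raise ValueError(f"protein {protein!r} has an empty domain set")

    @property
    def proteins(self) -> set[str]:
        return set(self.protein_to_domains)

    @property
    def domain_universe(self) -> set[str]:
        out: set[str] = set()
        for doms in self.protein_to_domains.values():
            out |= doms
        return out

    def domains_of(self, protein: str) -> frozenset[str]:
        return self.protein_to_domains[protein]

    def proteins_with_domain(self) -> dict[str, set[str]]:
        """Reverse index: domain accession -> set of proteins containing it."""
        index: dict[str, set[str]] = {}
        for protein, doms in self.protein_to_domains.items():
            for d in doms:
                index.setdefault(d, set()).add(protein)
        return index

    def __contains__(self, protein: str) -> bool:
        return protein in self.protein_to_domains

    def __len__(self) -> int:
        return len(self.protein_to_domains)


@dataclass(frozen=True)
class InteractionCatalog:
    """Deduplicated set of unordered, distinct-member protein pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self pair ({a},{b}) is not a valid SLGI")
            if a > b:
                raise ValueError(f"pair ({a},{b}) is not canonically ordered")

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))


@dataclass(frozen=True)
class FilterReport:
    """Stage-by-stage counts of the SLGI cleaning pipeline."""

    n_raw_pairs: int
    n_after_dedup: int
    n_after_domain_filter: int
    n_proteins_kept: int
    n_domains_kept: int

    def __post_init__(self) -> None:
        if not (
            self.n_raw_pairs >= self.n_after_dedup >= self.n_after_domain_filter
        ):
            raise ValueError("filter stages must be monotonically shrinking")


class ParseError(ValueError):
    """A malformed line in an input table (reported with its line number)."""


def _iter_rows(path: str | Path, min_fields: int) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    n_data = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields or any(
                not f.strip() for f in fields[:min_fields]
            ):
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_fields} tab-separated "
                    f"fields, got {line!r}"
                )
            n_data += 1
            yield lineno, [f.strip() for f in fields]
    if n_data == 0:
        raise ParseError(f"{path}: no data rows found")


def read_domain_assignments(path: str | Path) -> DomainAssignment:
    """Read a (protein, domain) TSV into a :class:`DomainAssignment`.

    Duplicate (protein, domain) rows collapse to one membership.
    """
    mapping: dict[str, set[str]] = {}
    for _, fields in _iter_rows(path, 2):
        protein, domain = fields[0], fields[1]
        mapping.setdefault(protein, set()).add(domain)
    return DomainAssignment({p: frozenset(d) for p, d in mapping.items()})


def read_interactions(path: str | Path) -> list[tuple[str, str]]:
    """Read raw ordered protein pairs, in file order, with no filtering."""
    return [(f[0], f[1]) for _, f in _iter_rows(path, 2)]


def read_domain_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column domain-pair TSV into a canonical unordered set.

    Used for iPfam-style physical-interaction lists and for edge lists;
    self pairs (d, d) are legal for domains.
    """
    return {canonical_pair(f[0], f[1]) for _, f in _iter_rows(path, 2)}


def filter_catalog(
    raw_pairs: Sequence[tuple[str, str]], assignments: DomainAssignment
) -> tuple[InteractionCatalog, FilterReport]:
    """Deduplicate raw SLGI pairs and drop pairs lacking domain annotation.

    Stage 1 merges unordered duplicates (storing (a,b) and (b,a) is one
    entry).  Stage 2 drops self pairs — a gene cannot be synthetic lethal
    with itself — and pairs where either protein has no assigned domain.
    """
    deduped = {canonical_pair(a, b) for a, b in raw_pairs}
    kept = frozenset(
        (a, b)
        for a, b in deduped
        if a != b and a in assignments and b in assignments
    )
    catalog = InteractionCatalog(kept)
    kept_proteins = catalog.proteins
    kept_domains: set[str] = set()
    for p in kept_proteins:
        kept_domains |= assignments.domains_of(p)
    report = FilterReport(
        n_raw_pairs=len(raw_pairs),
        n_after_dedup=len(deduped),
        n_after_domain_filter=len(kept),
        n_proteins_kept=len(kept_proteins),
        n_domains_kept=len(kept_domains),
    )
    return catalog, report


_PAIR_TABLE_COLUMNS = [
    "e_score",
    "probability",
    "domain_a",
    "domain_b",
    "n_proteins_a",
    "n_proteins_b",
    "n_slgi",
]


def write_domain_pair_table(
    stats: Iterable["DomainPairStats"], path: str | Path
) -> None:
    """Write per-domain-pair statistics, sorted by evidence score descending.

    Columns: evidence score, interaction probability, the two domain
    accessions, the number of proteins carrying each domain, and the number
    of SLGIs containing the pair.  Values round-trip through
    :func:`read_domain_pair_table` at 6 significant digits.
    """
    rows = sorted(stats, key=lambda s: (-s.escore, s.key))
    frame = pd.DataFrame(
        [
            {
                "e_score": f"{s.escore:.6g}",
                "probability": f"{s.theta:.6g}",
                "domain_a": s.key[0],
                "domain_b": s.key[1],
                "n_proteins_a": s.n_proteins_i,
                "n_proteins_b": s.n_proteins_j,
                "n_slgi": s.m0,
            }
            for s in rows
        ],
        columns=_PAIR_TABLE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_domain_pair_table(path: str | Path) -> list["DomainPairStats"]:
    from .evidence import DomainPairStats

    frame = pd.read_csv(path, sep="\t", dtype={"domain_a": str, "domain_b": str})
    return [
        DomainPairStats(
            key=canonical_pair(row.domain_a, row.domain_b),
            theta=float(row.probability),
            escore=float(row.e_score),
            m0=int(row.n_slgi),
            n_proteins_i=int(row.n_proteins_a),
            n_proteins_j=int(row.n_proteins_b),
        )
        for row in frame.itertuples()
    ]


def write_theta_table(
    theta: Mapping[tuple[str, str], float],
    counts: Mapping[tuple[str, str], object],
    path: str | Path,
) -> None:
    """Write fitted interaction probabilities with their M0/K counts."""
    rows = []
    for key in sorted(theta):
        c = counts.get(key)
        rows.append(
            {
                "domain_a": key[0],
                "domain_b": key[1],
                "probability": f"{theta[key]:.6g}",
                "n_slgi": getattr(c, "m0", ""),
                "n_noninteracting": getattr(c, "k", ""),
            }
        )
    pd.DataFrame(
        rows,
        columns=["domain_a", "domain_b", "probability", "n_slgi", "n_noninteracting"],
    ).to_csv(path, sep="\t", index=False)


def read_theta_table(path: str | Path) -> dict[tuple[str, str], float]:
    frame = pd.read_csv(path, sep="\t", dtype={"domain_a": str, "domain_b": str})
    return {
        canonical_pair(row.domain_a, row.domain_b): float(row.probability)
        for row in frame.itertuples()
    }


def write_predictions(records: Iterable, path: str | Path) -> None:
    """Stream prediction records to a TSV; records are written as they come."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tprobability\tis_novel\n")
        for rec in records:
            fh.write(
                f"{rec.protein_a}\t{rec.protein_b}\t"
                f"{rec.probability:.6g}\t{int(rec.is_novel)}\n"
            )


def write_report(items: Mapping[str, object], path: str | Path) -> None:
    """Write a ``key: value`` text report (network summary, overlap report)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for key, value in items.items():
            if isinstance(value, float) and math.isfinite(value):
                fh.write(f"{key}: {value:.6g}\n")
            else:
                fh.write(f"{key}: {value}\n")
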