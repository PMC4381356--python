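"""Representation-factor enrichment of gene lists against user-supplied
functional categories.

The representation factor is the observed overlap divided by the overlap
expected if the list and the category were drawn independently from the
universe; over-/under-representation p-values are hypergeometric tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    universe: int  # N
    list_size: int  # n1
    category_size: int  # n2
    overlap: int  # k
    expected: float
    rf: float
    p_over: float
    p_under: float

    @property
    def direction(self) -> str:
        return "over" if self.rf >= 1 else "under"


def _check_bounds(k: int, n1: int, n2: int, N: int) -> None:
    if not (0 < n1 <= N and 0 < n2 <= N):
        raise ValueError("need 0 < n1, n2 <= N")
    if not (0 <= k <= min(n1, n2)):
        raise ValueError("need 0 <= k <= min(n1, n2)")


def representation_factor(k: int, n1: int, n2: int, N: int) -> float:
    """rf = k * N / (n1 * n2): observed over expected overlap."""
    _check_bounds(k, n1, n2, N)
    return k * N / (n1 * n2)


def overlap_pvalue(k: int, n1: int, n2: int, N: int, direction: str = "over") -> float:
    """Hypergeometric tail for an overlap of k between sets of n1 and n2
    drawn from a universe of N: over = P(X >= k), under = P(X <= k)."""
    _check_bounds(k, n1, n2, N)
    if direction == "over":
        return float(hypergeom.sf(k - 1, N, n2, n1))
    if direction == "under":
        return float(hypergeom.cdf(k, N, n2, n1))
    raise ValueError("direction must be 'over' or 'under'")


def enrich_list(
    gene_list: set[str],
    categories: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One EnrichmentResult per category.

    Category memberships are intersected with the universe first; the gene
    list must be a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_list <= universe:
        raise ValueError("gene list not contained in universe")
    N = len(universe)
    n1 = len(gene_list)
    out = []
    for cat_id in sorted(categories):
        members = categories[cat_id] & universe
        n2 = len(members)
        if n1 == 0 or n2 == 0:
            continue
        k = len(gene_list & members)
        expected = n1 * n2 / N
        out.append(
            EnrichmentResult(
                category_id=cat_id,
                universe=N,
                list_size=n1,
                category_size=n2,
                overlap=k,
                expected=expected,
                rf=k / expected,
                p_over=overlap_pvalue(k, n1, n2, N, "over"),
                p_under=overlap_pvalue(k, n1, n2, N, "under"),
            )
        )
    return out


def results_frame(results: list[EnrichmentResult], alpha: float = 0.05) -> pd.DataFrame:
    rows = [
        (r.category_id, r.universe, r.list_size, r.category_size, r.overlap,
         r.expected, r.rf, r.p_over, r.p_under, r.direction,
         min(r.p_over, r.p_under) <= alpha)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["category_id", "N", "n1", "n2", "k", "expected", "rf",
                 "p_over", "p_under", "direction", "significant"],
    )


def read_categories(path: str | Path) -> dict[str, set[str]]:
    """Category memberships from two-column TSV (category_id, gene_id) or
    GMT (category, description, members...)."""
    path = Path(path)
    cats: dict[str, set[str]] = {}
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                cats.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
        return cats
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["category_id", "gene_id"], dtype=str)
    for cat, sub in df.groupby("category_id"):
        cats[cat] = set(sub["gene_id"])
    return cats
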