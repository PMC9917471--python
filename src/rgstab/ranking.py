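"""Meta-ranking: aggregate within-method stability rankings by the
geometric mean of ranks (the comprehensive "best overall gene" list).

Ranks are real numbers >= 1; ties in stability values may produce
non-integer average ranks. Aggregation ties are broken by the arithmetic
mean rank and then by gene name, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, IntegrityError

__all__ = [
    "MethodRanking",
    "ComprehensiveRanking",
    "assign_ranks",
    "geometric_mean_ranking",
    "subset_ranking",
    "ranking_from_order",
    "METHOD_SUBSETS",
]

#: method subsets by the input scale their estimators consume
METHOD_SUBSETS = {
    "CqE_methods": ("geNorm", "NormFinder"),
    "Cq_methods": ("BestKeeper", "DeltaCt"),
}


@dataclass
class MethodRanking:
    """One method's gene -> rank map (rank 1 = most stable)."""

    method: str
    ranks: dict[str, float]
    source: str = "computed"  # or "supplied"

    def __post_init__(self) -> None:
        k = len(self.ranks)
        total = sum(self.ranks.values())
        if not np.isclose(total, k * (k + 1) / 2):
            raise IntegrityError(
                f"{self.method}: ranks over {k} genes must sum to {k * (k + 1) / 2}, "
                f"got {total}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.ranks)


@dataclass
class ComprehensiveRanking:
    """Aggregated ranking: per-gene geometric mean of input ranks."""

    table: pd.DataFrame  # index: gene; columns: gm_rank, position
    inputs: list[str] = field(default_factory=list)

    @property
    def positions(self) -> dict[str, int]:
        return {g: int(p) for g, p in self.table["position"].items()}

    def gene_at(self, position: int) -> str:
        match = self.table.index[self.table["position"] == position]
        if len(match) != 1:
            raise KeyError(position)
        return match[0]

    def to_csv(self, path) -> None:
        out = self.table.sort_values("position")
        out.to_csv(path, index_label="gene")


def assign_ranks(
    stability: dict[str, float] | pd.Series,
    method: str = "",
    tie_policy: str = "strict_order",
) -> MethodRanking:
    """Rank genes by ascending stability value (1 = most stable).

    ``tie_policy='average'`` gives tied values the mean of their positions;
    ``'strict_order'`` breaks ties by gene name (deterministic).
    """
    sv = pd.Series(dict(stability), dtype=float)
    if sv.isna().any():
        raise DomainError(f"NaN stability value for {list(sv.index[sv.isna()])}")
    if tie_policy == "average":
        ranks = pd.Series(stats.rankdata(sv.to_numpy(), method="average"), index=sv.index)
    elif tie_policy == "strict_order":
        ordered = sorted(sv.index, key=lambda g: (sv[g], g))
        ranks = pd.Series({g: float(i + 1) for i, g in enumerate(ordered)})
    else:
        raise DomainError(f"unknown tie_policy {tie_policy!r}")
    return MethodRanking(method=method, ranks=ranks.to_dict(), source="computed")


def ranking_from_order(method: str, order: list[str]) -> MethodRanking:
    """Build a MethodRanking from an explicit most-stable-first gene order."""
    return MethodRanking(
        method=method,
        ranks={g: float(i + 1) for i, g in enumerate(order)},
        source="supplied",
    )


def geometric_mean_ranking(rankings: list[MethodRanking]) -> ComprehensiveRanking:
    """Aggregate >= 2 rankings over one gene set by geometric mean of ranks.

    Position ties (equal geometric means) are broken by ascending
    arithmetic mean rank, then by gene name.
    """
    if len(rankings) < 2:
        raise DomainError("need >= 2 method rankings")
    gene_sets = {r.genes for r in rankings}
    if len(gene_sets) != 1:
        all_genes = frozenset().union(*gene_sets)
        common = frozenset.intersection(*gene_sets)
        raise IntegrityError(
            f"gene-set mismatch across methods: {sorted(all_genes - common)}"
        )
    genes = sorted(next(iter(gene_sets)))
    mat = pd.DataFrame({r.method or i: r.ranks for i, r in enumerate(rankings)}).loc[genes]
    gm = np.exp(np.log(mat).mean(axis=1))
    am = mat.mean(axis=1)
    order = sorted(genes, key=lambda g: (gm[g], am[g], g))
    table = pd.DataFrame(
        {
            "gm_rank": gm,
            "position": pd.Series({g: i + 1 for i, g in enumerate(order)}),
        }
    ).loc[order]
    return ComprehensiveRanking(table=table, inputs=[r.method for r in rankings])


def subset_ranking(
    rankings: list[MethodRanking], subset: str
) -> ComprehensiveRanking:
    """Aggregate only the methods of a named subset (``CqE_methods`` =
    geNorm + NormFinder; ``Cq_methods`` = BestKeeper + DeltaCt)."""
    if subset not in METHOD_SUBSETS:
        raise DomainError(f"unknown subset {subset!r}; options: {list(METHOD_SUBSETS)}")
    wanted = METHOD_SUBSETS[subset]
    chosen = [r for r in rankings if r.method in wanted]
    present = {r.method for r in chosen}
    missing = [m for m in wanted if m not in present]
    if missing:
        raise DomainError(f"subset {subset} needs method(s): {missing}")
    return geometric_mean_ranking(chosen)
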