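"""End-to-end stability workflow shared by the CLI and the tests.

The default scale policy mirrors the study design: geNorm and NormFinder
consume efficiency-corrected cycles (geNorm as base-2 relative
quantities), while BestKeeper and the comparative delta-Ct method consume
mean raw Cq.
"""

from __future__ import annotations

import pandas as pd

from .errors import DomainError
from .qpcr import (
    CqTable,
    average_technical_replicates,
    efficiency_correct,
    to_relative_quantity,
)
from .ranking import ComprehensiveRanking, MethodRanking, assign_ranks, geometric_mean_ranking
from .stability import bestkeeper, delta_ct, genorm, normfinder

__all__ = ["stability_workflow", "comprehensive_from_stability", "ALL_METHODS"]

ALL_METHODS = ("geNorm", "NormFinder", "BestKeeper", "DeltaCt")


def stability_workflow(
    table: CqTable,
    methods: tuple[str, ...] = ALL_METHODS,
    efficiencies: dict[str, float] | None = None,
    use_efficiency: bool = True,
    tie_policy: str = "strict_order",
):
    """Run the requested estimators on a Cq table.

    Returns ``(results, rankings)``: per-method result objects and
    :class:`MethodRanking` built from the unrounded stability values.
    ``use_efficiency=False`` runs geNorm/NormFinder on uncorrected Cq
    (equivalent to E = 2 everywhere).
    """
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise DomainError(f"unknown method(s): {unknown}")
    if not methods:
        raise DomainError("method list must be non-empty")

    cq = average_technical_replicates(table)
    needs_eff = use_efficiency and bool({"geNorm", "NormFinder"} & set(methods))
    if needs_eff:
        eff = efficiencies if efficiencies is not None else table.efficiencies()
        if eff is None:
            raise DomainError(
                "geNorm/NormFinder need efficiencies; pass use_efficiency=False "
                "to run uncorrected"
            )
        cqe = efficiency_correct(cq, eff)
    else:
        cqe = cq

    results: dict[str, object] = {}
    stability: dict[str, pd.Series] = {}
    for m in methods:
        if m == "geNorm":
            res = genorm(to_relative_quantity(cqe, base=2.0))
            stability[m] = res.m_value
        elif m == "NormFinder":
            res = normfinder(cqe)
            stability[m] = res.stability
        elif m == "BestKeeper":
            res = bestkeeper(cq)
            stability[m] = res.stability
        else:
            res = delta_ct(cq)
            stability[m] = res.stability
        results[m] = res

    rankings = [
        assign_ranks(stability[m], method=m, tie_policy=tie_policy) for m in methods
    ]
    # geNorm ranks follow the exclusion order, not the recorded M values
    # (mid-run M values are not comparable across steps)
    if "geNorm" in methods:
        order = results["geNorm"].ranking()
        idx = [m for m in methods].index("geNorm")
        rankings[idx] = MethodRanking(
            method="geNorm",
            ranks={g: float(i + 1) for i, g in enumerate(order)},
            source="computed",
        )
    return results, rankings


def comprehensive_from_stability(
    rankings: list[MethodRanking],
) -> ComprehensiveRanking:
    """Aggregate computed method rankings into the comprehensive ranking."""
    return geometric_mean_ranking(rankings)
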