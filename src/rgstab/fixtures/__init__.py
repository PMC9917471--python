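"""Bundled plain-text fixtures.

``method_rank_orders.csv`` holds the published within-method stability
rank orders of six lettuce candidate reference genes for three
experiments (leaf-colour comparison, tissue comparison, drought stress),
one row per (experiment, method, rank, gene). The deterministic
simulated Cq table and count matrix are regenerated by
``scripts/make_fixtures.py``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..ranking import MethodRanking

__all__ = ["fixture_path", "load_method_rank_orders", "EXPERIMENTS"]

EXPERIMENTS = ("green_vs_red", "leaf_vs_stem", "drought")


def fixture_path(name: str):
    """Filesystem path of a bundled fixture file."""
    return resources.files(__package__) / "data" / name


def load_method_rank_orders() -> dict[str, list[MethodRanking]]:
    """Per experiment, the four supplied method rankings (rank 1 first)."""
    df = pd.read_csv(fixture_path("method_rank_orders.csv"))
    out: dict[str, list[MethodRanking]] = {}
    for exp, sub in df.groupby("experiment", sort=False):
        rankings = []
        for method, block in sub.groupby("method", sort=False):
            ranks = dict(zip(block["gene"], block["rank"].astype(float)))
            rankings.append(MethodRanking(method=method, ranks=ranks, source="supplied"))
        out[exp] = rankings
    return out
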