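"""Expression-stability estimators for candidate reference genes.

Four independent estimators, each mapping an :class:`~rgstab.qpcr.ExpressionMatrix`
to per-gene stability values (lower = more stable) and a within-method
ranking:

- :func:`genorm`      — mean pairwise variation (M) with stepwise exclusion;
                        consumes relative quantities.
- :func:`normfinder`  — ANOVA-style intra/inter-group variance decomposition;
                        consumes cycle-scale values (Cq or CqE).
- :func:`bestkeeper`  — descriptive index: SD, CV and correlation with the
                        per-sample geometric-mean index; consumes raw Cq.
- :func:`delta_ct`    — mean over partner genes of the SD of pairwise Cq
                        differences; consumes raw Cq.

All standard deviations use the n-1 denominator. Every estimator is
invariant under adding a per-gene constant on the cycle scale (for
BestKeeper the ranking statistic, the SD, is; the CV shifts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .qpcr import ExpressionMatrix, Scale

__all__ = [
    "GeNormResult",
    "NormFinderResult",
    "BestKeeperResult",
    "DeltaCtResult",
    "genorm",
    "normfinder",
    "bestkeeper",
    "delta_ct",
    "ESTIMATORS",
]


def _check_scale(matrix: ExpressionMatrix, expected: tuple[Scale, ...], method: str) -> None:
    if matrix.scale not in expected:
        warnings.warn(
            f"{method} normally consumes scale in {[s.value for s in expected]}, "
            f"got {matrix.scale.value}; proceeding",
            stacklevel=3,
        )


@dataclass
class GeNormResult:
    """Stepwise-exclusion output of :func:`genorm`.

    ``m_value[g]`` is the gene's M at the step it was excluded; the final,
    most stable pair shares the two-gene M (their mutual pairwise
    variation). ``exclusion_order`` lists genes from least to most stable.
    """

    m_value: pd.Series
    exclusion_order: list[str]
    pairwise_v: pd.Series | None = None

    @property
    def stability(self) -> pd.Series:
        return self.m_value

    def ranking(self) -> list[str]:
        """Most stable first."""
        return list(reversed(self.exclusion_order))


@dataclass
class NormFinderResult:
    """Variance-decomposition output of :func:`normfinder`."""

    stability: pd.Series
    intra_var: pd.DataFrame  # genes x groups, intragroup variance estimates
    inter_dev: pd.DataFrame | None = None  # genes x groups, raw intergroup deviations

    def ranking(self) -> list[str]:
        return list(self.stability.sort_values(kind="stable").index)


@dataclass
class BestKeeperResult:
    """Descriptive statistics of :func:`bestkeeper`; ranking uses ``sd_cq``."""

    table: pd.DataFrame  # per gene: sd_cq, cv_pct, r_index, geo_mean, arith_mean, min, max
    index: pd.Series  # per-sample geometric mean of Cq across genes

    @property
    def stability(self) -> pd.Series:
        return self.table["sd_cq"]

    def ranking(self) -> list[str]:
        return list(self.stability.sort_values(kind="stable").index)


@dataclass
class DeltaCtResult:
    """Pairwise-SD output of :func:`delta_ct`."""

    stability: pd.Series
    pair_sd: pd.DataFrame  # symmetric gene x gene, zero diagonal

    def ranking(self) -> list[str]:
        return list(self.stability.sort_values(kind="stable").index)


# ---------------------------------------------------------------------------
# geNorm


def _pairwise_variation_matrix(log_q: pd.DataFrame) -> pd.DataFrame:
    """V[j, k] = SD over samples of log2(Q_j / Q_k), n-1 denominator."""
    genes = list(log_q.index)
    arr = log_q.to_numpy()
    k = len(genes)
    v = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sd = float(np.std(arr[i] - arr[j], ddof=1))
            v[i, j] = v[j, i] = sd
    return pd.DataFrame(v, index=genes, columns=genes)


def _m_values(v: pd.DataFrame) -> pd.Series:
    k = len(v)
    return v.sum(axis=1) / (k - 1)


def genorm(
    matrix: ExpressionMatrix, compute_pairwise_v: bool = True
) -> GeNormResult:
    """geNorm expression-stability M with stepwise exclusion.

    For genes j, k let A_jk(s) = log2(Q_j(s)/Q_k(s)); the pairwise
    variation V_jk is the sample SD of A_jk and M_j is the mean of V_jk
    over all partners k. The gene with the largest M is excluded (its M
    recorded), M is recomputed, and so on until two genes remain; those
    share the final two-gene M. Ties on the worst M are broken by removing
    the lexicographically last gene name (deterministic).

    When ``compute_pairwise_v`` is set, V_n/n+1 (SD of the log2 ratio of
    normalization factors built from the n and n+1 most stable genes) is
    reported for n = 2..k-1; no gene-count cutoff is applied.
    """
    if matrix.scale is not Scale.QUANTITY:
        raise DomainError("genorm requires a QUANTITY-scale matrix")
    if len(matrix.genes) < 3:
        raise DomainError("genorm needs >= 3 genes")
    if len(matrix.samples) < 2:
        raise DomainError("genorm needs >= 2 samples")
    if (matrix.values.to_numpy() <= 0).any():
        raise DomainError("quantities must be strictly positive")

    log_q = np.log2(matrix.values)
    m_value: dict[str, float] = {}
    exclusion_order: list[str] = []
    remaining = log_q.copy()
    while len(remaining) > 2:
        v = _pairwise_variation_matrix(remaining)
        m = _m_values(v)
        worst_m = m.max()
        # lexicographically last among the tied worst
        worst = sorted(m.index[m == worst_m])[-1]
        m_value[worst] = float(worst_m)
        exclusion_order.append(worst)
        remaining = remaining.drop(index=worst)
    final_pair = sorted(remaining.index)
    final_m = float(np.std(remaining.iloc[0] - remaining.iloc[1], ddof=1))
    for g in final_pair:
        m_value[g] = final_m
    # least stable of the final pair listed first; tie -> lexicographic
    exclusion_order.extend(sorted(final_pair, reverse=True))

    pairwise_v = None
    if compute_pairwise_v and len(matrix.genes) > 3:
        order = list(reversed(exclusion_order))  # most stable first
        vs = {}
        for n in range(2, len(order)):
            nf_n = log_q.loc[order[:n]].mean(axis=0)  # log2 geometric mean
            nf_n1 = log_q.loc[order[: n + 1]].mean(axis=0)
            vs[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
        pairwise_v = pd.Series(vs)

    return GeNormResult(
        m_value=pd.Series(m_value).reindex(matrix.genes),
        exclusion_order=exclusion_order,
        pairwise_v=pairwise_v,
    )


# ---------------------------------------------------------------------------
# NormFinder


def normfinder(
    matrix: ExpressionMatrix,
    groups: dict[str, str] | None = None,
    shrink: bool = True,
) -> NormFinderResult:
    """NormFinder stability via intra/inter-group variance decomposition.

    Steps, on cycle-scale values y (Cq or CqE, both log-like):

    1. sample-center: z_g(s) = y_g(s) - mean over genes of y(., s);
    2. per group j and gene g, the intragroup variance estimate is
       sigma2_gj = max(0, (s2_gj - S_j / k^2) / (1 - 2/k)) with
       s2_gj the within-group sample variance of z_g and
       S_j = (k/(k-1)) * sum_g s2_gj;
    3. with >= 2 groups, the intergroup deviation d_gj (group mean of z_g
       minus its mean over groups) is shrunk towards zero by the
       empirical-Bayes factor sigma2_d / (sigma2_d + sigma2_gj / n_j);
    4. stability(g) = mean over groups of |d~_gj| + sqrt(sigma2_gj / n_j);
       with one group, stability(g) = sqrt(sigma2_g).

    ``shrink=False`` skips step 3's shrinkage (some reimplementations
    omit it); the raw deviations are then used directly.
    """
    _check_scale(matrix, (Scale.CQE, Scale.CQ), "normfinder")
    genes = matrix.genes
    k = len(genes)
    if k < 3:
        raise DomainError("normfinder needs >= 3 genes")
    groups = groups or matrix.groups
    if not groups:
        groups = {s: "all" for s in matrix.samples}
    labels = sorted(set(groups[s] for s in matrix.samples))
    members = {j: [s for s in matrix.samples if groups[s] == j] for j in labels}
    for j, ss in members.items():
        if len(ss) < 2:
            raise DomainError(f"group {j} has < 2 samples")
    n_groups = len(labels)

    z = matrix.values - matrix.values.mean(axis=0)

    s2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for j in labels:
        s2[j] = z[members[j]].var(axis=1, ddof=1)
    sigma2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for j in labels:
        s_j = (k / (k - 1)) * s2[j].sum()
        sigma2[j] = ((s2[j] - s_j / k**2) / (1 - 2 / k)).clip(lower=0.0)

    n_j = pd.Series({j: len(members[j]) for j in labels}, dtype=float)

    if n_groups == 1:
        j = labels[0]
        stability = np.sqrt(sigma2[j])
        stability.name = None
        return NormFinderResult(stability=stability, intra_var=sigma2, inter_dev=None)

    a = pd.DataFrame(index=genes, columns=labels, dtype=float)
    for j in labels:
        a[j] = z[members[j]].mean(axis=1)
    d = a.sub(a.mean(axis=1), axis=0)

    noise = sigma2.div(n_j, axis=1)  # sigma2_gj / n_j
    if shrink:
        var_d = float(np.var(d.to_numpy(), ddof=1))
        sigma2_d = max(0.0, var_d - float(noise.to_numpy().mean()))
        denom = sigma2_d + noise
        # fully degenerate data (no variation at all): shrink to zero
        gamma = (sigma2_d / denom.where(denom > 0, np.inf)).fillna(0.0)
        d_tilde = d * gamma
    else:
        d_tilde = d

    stability = (d_tilde.abs() + np.sqrt(noise)).mean(axis=1)
    stability.name = None
    return NormFinderResult(stability=stability, intra_var=sigma2, inter_dev=d)


# ---------------------------------------------------------------------------
# BestKeeper


def bestkeeper(matrix: ExpressionMatrix) -> BestKeeperResult:
    """BestKeeper descriptive stability: per-gene Cq SD, CV%, and the
    correlation of each gene with the per-sample geometric-mean index.

    The ranking statistic is the SD of Cq alone; CV and r are reported.
    """
    _check_scale(matrix, (Scale.CQ,), "bestkeeper")
    if len(matrix.samples) < 2:
        raise DomainError("bestkeeper needs >= 2 samples")
    vals = matrix.values
    if (vals.to_numpy() <= 0).any():
        raise DomainError("Cq values must be > 0")

    index = np.exp(np.log(vals).mean(axis=0))  # geometric mean per sample
    rows = {}
    for g in matrix.genes:
        x = vals.loc[g]
        sd = float(x.std(ddof=1))
        mean = float(x.mean())
        if mean == 0:
            raise DomainError(f"zero mean Cq for gene {g}")
        if x.nunique() == 1 or index.nunique() == 1:
            r = 1.0 if len(matrix.genes) == 1 else float("nan")
        else:
            r = float(np.corrcoef(x, index)[0, 1])
        rows[g] = {
            "sd_cq": sd,
            "cv_pct": 100.0 * sd / mean,
            "r_index": r,
            "geo_mean": float(np.exp(np.log(x).mean())),
            "arith_mean": mean,
            "min": float(x.min()),
            "max": float(x.max()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(matrix.genes)
    return BestKeeperResult(table=table, index=index)


# ---------------------------------------------------------------------------
# comparative delta-Ct


def delta_ct(matrix: ExpressionMatrix) -> DeltaCtResult:
    """Comparative delta-Ct stability.

    For every gene pair (g, h) compute the per-sample Cq difference and
    its SD across samples; a gene's stability is the mean of those SDs
    over all its partners.
    """
    _check_scale(matrix, (Scale.CQ,), "delta_ct")
    genes = matrix.genes
    if len(genes) < 2:
        raise DomainError("delta_ct needs >= 2 genes")
    if len(matrix.samples) < 2:
        raise DomainError("delta_ct needs >= 2 samples")
    arr = matrix.values.to_numpy()
    k = len(genes)
    pair = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sd = float(np.std(arr[i] - arr[j], ddof=1))
            pair[i, j] = pair[j, i] = sd
    pair_sd = pd.DataFrame(pair, index=genes, columns=genes)
    stability = pair_sd.sum(axis=1) / (k - 1)
    return DeltaCtResult(stability=stability, pair_sd=pair_sd)


#: method label -> (callable, expected input scale policy)
ESTIMATORS = {
    "geNorm": genorm,
    "NormFinder": normfinder,
    "BestKeeper": bestkeeper,
    "DeltaCt": delta_ct,
}
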