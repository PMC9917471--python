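"""RNA-seq candidate reference-gene screening.

A candidate must look *non*-differentially expressed everywhere: small
absolute log2 fold change, non-significant FDR, wide coverage, and
non-significant ANOVA / t-test on its counts across the groups of every
experiment. The differential-expression table (gene, log2fc, fdr,
mean_count) is an upstream input; nothing before it is recomputed here.

Counts are tested on a counts-per-million (CPM) scale by default so that
library-size differences do not masquerade as group effects; pass
``normalize=False`` to test raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FormatError, IntegrityError

__all__ = [
    "DETable",
    "CountMatrix",
    "ScreenTable",
    "read_de_table",
    "read_count_matrix",
    "filter_de_stability",
    "filter_coverage",
    "anova_counts",
    "ttest_counts",
    "select_candidates",
    "significance_code",
]

DE_COLUMNS = ("gene", "log2fc", "fdr", "mean_count")


@dataclass
class DETable:
    """Per-gene differential-expression summary for one experiment."""

    data: pd.DataFrame  # columns: gene, log2fc, fdr, mean_count

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"DE table missing column(s): {', '.join(missing)}")
        df = self.data.copy()
        if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
            raise DomainError("fdr must lie in [0, 1]")
        if (df["mean_count"] < 0).any():
            raise DomainError("mean_count must be >= 0")
        if df["gene"].duplicated().any():
            raise IntegrityError("duplicated gene in DE table")
        self.data = df.set_index("gene", drop=False)

    @property
    def genes(self) -> list[str]:
        return list(self.data["gene"])


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus a sample->group map."""

    counts: pd.DataFrame
    groups: dict[str, str]
    experiment_id: str = ""

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DomainError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise DomainError("counts must be integers")
        uncovered = [s for s in self.counts.columns if s not in self.groups]
        if uncovered:
            raise IntegrityError(f"design does not cover sample(s): {uncovered}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def values_for_test(self, normalize: bool = True) -> pd.DataFrame:
        """Counts, CPM-normalized per sample unless ``normalize=False``."""
        if not normalize:
            return self.counts.astype(float)
        libsize = self.counts.sum(axis=0)
        if (libsize == 0).any():
            raise DomainError("zero library size; cannot CPM-normalize")
        return self.counts.div(libsize, axis=1) * 1e6


@dataclass
class ScreenTable:
    """Every component decision of the screen, one row per gene."""

    data: pd.DataFrame
    experiments: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return sorted(self.data.index[self.data["selected"]])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="gene")


def read_de_table(path) -> DETable:
    return DETable(pd.read_csv(path))


def read_count_matrix(counts_path, design_path, experiment_id: str = "") -> CountMatrix:
    """Read a genes x samples TSV and a two-column (sample_id, group) design."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    if not {"sample_id", "group"} <= set(design.columns):
        raise FormatError("design file needs columns sample_id, group")
    groups = dict(design[["sample_id", "group"]].itertuples(index=False, name=None))
    return CountMatrix(counts=counts, groups=groups, experiment_id=experiment_id)


def filter_de_stability(
    de: DETable, max_abs_log2fc: float = 1.0, min_fdr: float = 0.05
) -> set[str]:
    """Genes that are NOT differentially expressed.

    Keeps genes with ``|log2fc| <= max_abs_log2fc`` and ``fdr >= min_fdr``
    (a high adjusted p-value means no evidence of expression change).
    """
    df = de.data
    keep = (df["log2fc"].abs() <= max_abs_log2fc) & (df["fdr"] >= min_fdr)
    return set(df.loc[keep, "gene"])


def filter_coverage(de: DETable, min_mean_count: float) -> set[str]:
    """Genes with mean count (coverage proxy) at or above the threshold."""
    if min_mean_count < 0:
        raise DomainError("min_mean_count must be >= 0")
    df = de.data
    return set(df.loc[df["mean_count"] >= min_mean_count, "gene"])


def _grouped_values(counts: CountMatrix, gene: str, normalize: bool) -> list[np.ndarray]:
    if gene not in counts.counts.index:
        raise IntegrityError(f"gene {gene} not in count matrix")
    vals = counts.values_for_test(normalize).loc[gene]
    return [
        vals[[s for s in counts.counts.columns if counts.groups[s] == g]].to_numpy()
        for g in counts.group_labels()
    ]


def anova_counts(counts: CountMatrix, gene: str, normalize: bool = True) -> float:
    """One-way fixed-effects ANOVA p-value for a gene's counts across groups.

    Degenerate input (zero variance everywhere, equal means) returns p = 1.
    """
    groups = _grouped_values(counts, gene, normalize)
    if len(groups) < 2:
        raise DomainError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise DomainError("every group needs >= 2 samples")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g[0] for g in groups]
        if np.ptp(means) == 0:
            return 1.0
        return 0.0
    return float(stats.f_oneway(*groups).pvalue)


def ttest_counts(counts: CountMatrix, gene: str, normalize: bool = True) -> float:
    """Two-sided equal-variance (Student) two-sample t-test p-value."""
    groups = _grouped_values(counts, gene, normalize)
    if len(groups) != 2:
        raise DomainError("t-test needs exactly 2 groups")
    if any(len(g) < 2 for g in groups):
        raise DomainError("every group needs >= 2 samples")
    a, b = groups
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def significance_code(p: float, alpha: float = 0.05, strict: float = 0.01) -> str:
    """ns / * / ** coding of a p-value at the 0.05 / 0.01 levels."""
    if p < strict:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def select_candidates(
    de_tables: dict[str, DETable],
    count_matrices: dict[str, CountMatrix],
    *,
    max_abs_log2fc: float = 1.0,
    min_fdr: float = 0.05,
    min_mean_count: float = 100.0,
    alpha: float = 0.05,
    normalize: bool = True,
) -> ScreenTable:
    """Run the full screen over several experiments.

    A gene is selected iff in EVERY experiment it passes the DE-stability
    filter, the coverage filter, and shows a non-significant ANOVA (and,
    for two-group experiments, a non-significant t-test) at ``alpha``.
    All per-experiment component decisions are recorded.
    """
    if not de_tables:
        raise DomainError("at least one experiment required")
    universes = {exp: frozenset(t.genes) for exp, t in de_tables.items()}
    reference = next(iter(universes.values()))
    bad = {
        exp: sorted(u ^ reference) for exp, u in universes.items() if u != reference
    }
    for exp, cm in count_matrices.items():
        if frozenset(cm.genes) != reference:
            bad[exp] = sorted(frozenset(cm.genes) ^ reference)
    if bad:
        raise IntegrityError(f"gene universe mismatch: {bad}")

    genes = sorted(reference)
    rows: dict[str, dict] = {g: {} for g in genes}
    experiments = sorted(de_tables)
    for exp in experiments:
        de = de_tables[exp]
        kept_de = filter_de_stability(de, max_abs_log2fc, min_fdr)
        kept_cov = filter_coverage(de, min_mean_count)
        cm = count_matrices.get(exp)
        for g in genes:
            rows[g][f"{exp}_passed_de"] = g in kept_de
            rows[g][f"{exp}_passed_coverage"] = g in kept_cov
            if cm is not None:
                p = anova_counts(cm, g, normalize)
                rows[g][f"{exp}_anova_p"] = p
                rows[g][f"{exp}_anova_code"] = significance_code(p, alpha)
                rows[g][f"{exp}_passed_anova"] = p >= alpha
                if len(cm.group_labels()) == 2:
                    tp = ttest_counts(cm, g, normalize)
                    rows[g][f"{exp}_t_p"] = tp
                    rows[g][f"{exp}_t_code"] = significance_code(tp, alpha)
                    rows[g][f"{exp}_passed_t"] = tp >= alpha

    df = pd.DataFrame.from_dict(rows, orient="index")
    flag_cols = [c for c in df.columns if c.startswith(tuple(f"{e}_passed" for e in experiments))]
    df["selected"] = df[flag_cols].all(axis=1)
    return ScreenTable(data=df, experiments=experiments)
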