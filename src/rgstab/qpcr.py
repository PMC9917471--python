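"""qPCR Cq data: loading, validation, transforms, and distribution summaries.

The module is organised around two containers:

``CqTable``
    Long-format quantification-cycle (Cq) measurements — one row per
    (sample, gene, technical replicate) — with an optional per-gene
    amplification efficiency ``E`` (1 < E <= 2, where 2 is perfect
    doubling).

``ExpressionMatrix``
    A gene x sample matrix on one of three declared scales:

    - ``CQ``       raw quantification cycles (log-scale by nature),
    - ``CQE``      efficiency-corrected cycles, ``CqE = Cq * log(E)/log(2)``,
    - ``QUANTITY`` relative quantities ``Q = base**(minCq - Cq)`` per gene.

Conventions (documented because they differ across tools):

- technical replicates are averaged arithmetically on the Cq scale;
- quartiles use linear interpolation between order statistics;
- outliers use the Tukey 1.5 x IQR rule and whiskers span the non-outliers;
- there is no silent default efficiency — pass ``E = 2`` explicitly to
  reproduce an uncorrected pipeline.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CompletenessError, DomainError, FormatError, IntegrityError

__all__ = [
    "Scale",
    "CqTable",
    "ExpressionMatrix",
    "DistributionSummary",
    "read_cq_table",
    "average_technical_replicates",
    "efficiency_correct",
    "to_relative_quantity",
    "summarize_distribution",
]

REQUIRED_COLUMNS = ("sample_id", "group", "gene", "replicate", "cq")
OPTIONAL_COLUMNS = ("efficiency",)


class Scale(str, enum.Enum):
    """Declared scale of an :class:`ExpressionMatrix`."""

    CQ = "CQ"
    CQE = "CQE"
    QUANTITY = "QUANTITY"


@dataclass
class CqTable:
    """Validated long-format qPCR measurements.

    Parameters
    ----------
    data:
        One row per (sample_id, group, gene, replicate) with a finite
        positive ``cq`` and an optional ``efficiency`` column.
    experiment_id:
        Free-text label carried through to outputs.
    """

    data: pd.DataFrame
    experiment_id: str = ""

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
        bad = df.index[df["cq"].isna() | ~np.isfinite(df["cq"]) | (df["cq"] <= 0)]
        if len(bad):
            raise DomainError(
                f"cq must be finite and > 0; offending row index(es): {list(bad[:5])}"
            )
        dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            rows = df.loc[dup, ["sample_id", "gene", "replicate"]].iloc[0]
            raise IntegrityError(
                "duplicated (sample, gene, replicate) triple: "
                f"({rows['sample_id']}, {rows['gene']}, {rows['replicate']})"
            )
        ngroups = df.groupby("sample_id", sort=False)["group"].nunique()
        conflicted = ngroups[ngroups > 1]
        if len(conflicted):
            raise IntegrityError(
                "sample(s) mapped to more than one group: "
                + ", ".join(map(str, conflicted.index))
            )
        if "efficiency" in df.columns:
            eff = pd.to_numeric(df["efficiency"], errors="coerce")
            known = eff.dropna()
            if ((known <= 1) | (known > 2)).any():
                raise DomainError("efficiency must satisfy 1 < E <= 2")
            df["efficiency"] = eff
            per_gene = df.dropna(subset=["efficiency"]).groupby("gene")[
                "efficiency"
            ].nunique()
            if (per_gene > 1).any():
                genes = per_gene[per_gene > 1].index
                raise IntegrityError(
                    "efficiency must be constant per gene; offending gene(s): "
                    + ", ".join(map(str, genes))
                )
        self.data = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        # keep file order for samples, it usually encodes the design
        return list(pd.unique(self.data["sample_id"]))

    @property
    def groups(self) -> dict[str, str]:
        """sample_id -> group label."""
        return dict(
            self.data.drop_duplicates("sample_id")[["sample_id", "group"]].itertuples(
                index=False, name=None
            )
        )

    def efficiencies(self) -> dict[str, float] | None:
        """Per-gene efficiency map, or None when the column is absent/empty."""
        if "efficiency" not in self.data.columns:
            return None
        known = self.data.dropna(subset=["efficiency"])
        if known.empty:
            return None
        return dict(
            known.drop_duplicates("gene")[["gene", "efficiency"]].itertuples(
                index=False, name=None
            )
        )


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with a declared scale and a sample->group map."""

    values: pd.DataFrame  # genes as rows, samples as columns
    scale: Scale
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.values.isna().any().any():
            cells = [
                (g, s)
                for g in self.values.index
                for s in self.values.columns
                if pd.isna(self.values.at[g, s])
            ]
            raise CompletenessError(f"missing cell(s): {cells[:10]}")
        if self.scale is Scale.QUANTITY and (self.values.to_numpy() <= 0).any():
            raise DomainError("QUANTITY-scale matrix must be strictly positive")
        if self.groups:
            uncovered = [s for s in self.values.columns if s not in self.groups]
            if uncovered:
                raise IntegrityError(f"group map does not cover sample(s): {uncovered}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        """Write matrix CSV with a ``# scale=...`` / ``# groups=...`` header."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# scale={self.scale.value}\n")
            if self.groups:
                pairs = ";".join(f"{s}:{g}" for s, g in self.groups.items())
                fh.write(f"# groups={pairs}\n")
            self.values.to_csv(fh, index_label="gene")

    @classmethod
    def from_csv(cls, path) -> "ExpressionMatrix":
        scale = Scale.CQ
        groups: dict[str, str] = {}
        body: list[str] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("# scale="):
                    scale = Scale(line.strip().split("=", 1)[1])
                elif line.startswith("# groups="):
                    pairs = line.strip().split("=", 1)[1]
                    groups = dict(p.split(":", 1) for p in pairs.split(";") if p)
                else:
                    body.append(line)
        values = pd.read_csv(io.StringIO("".join(body)), index_col="gene")
        values.index.name = None
        return cls(values=values, scale=scale, groups=groups)


@dataclass
class DistributionSummary:
    """Per-gene five-number-style summary of Cq values (boxplot statistics)."""

    gene: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def read_cq_table(path, *, sep: str | None = None, experiment_id: str = "") -> CqTable:
    """Read a long-format delimited Cq file into a validated :class:`CqTable`.

    The delimiter is sniffed from the extension (``.tsv`` -> tab, else comma)
    unless ``sep`` is given. Unknown columns are preserved.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    non_numeric = pd.to_numeric(df["cq"], errors="coerce").isna() & df["cq"].notna()
    if non_numeric.any():
        row = int(df.index[non_numeric][0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: non-numeric cq at file row {row}")
    return CqTable(data=df, experiment_id=experiment_id)


def average_technical_replicates(table: CqTable) -> ExpressionMatrix:
    """Average technical-replicate Cq values into a gene x sample CQ matrix.

    Each cell is the arithmetic mean of that (gene, sample) pair's
    replicates; a pair with no replicates at all is a completeness error.
    Idempotent on already-averaged data (single replicate per pair).
    """
    df = table.data
    wide = df.pivot_table(
        index="gene", columns="sample_id", values="cq", aggfunc="mean", sort=False
    )
    wide = wide.reindex(index=table.genes, columns=table.samples)
    if wide.isna().any().any():
        pairs = [
            (g, s) for g in wide.index for s in wide.columns if pd.isna(wide.at[g, s])
        ]
        raise CompletenessError(f"no replicates for (gene, sample) pair(s): {pairs}")
    wide.columns.name = None
    wide.index.name = None
    return ExpressionMatrix(values=wide, scale=Scale.CQ, groups=table.groups)


def efficiency_correct(
    matrix: ExpressionMatrix, efficiencies: dict[str, float]
) -> ExpressionMatrix:
    """Efficiency-correct a CQ matrix: ``CqE = Cq * log(E) / log(2)``.

    ``E = 2`` (perfect doubling) is the identity. Every gene needs an
    explicit efficiency in ``(1, 2]``; there is no default.
    """
    if matrix.scale is not Scale.CQ:
        raise DomainError(f"efficiency_correct expects scale=CQ, got {matrix.scale}")
    missing = [g for g in matrix.genes if g not in efficiencies]
    if missing:
        raise DomainError(f"missing efficiency for gene(s): {missing}")
    for g in matrix.genes:
        e = efficiencies[g]
        if not (1 < e <= 2):
            raise DomainError(f"efficiency for gene {g} must satisfy 1 < E <= 2, got {e}")
    factors = pd.Series(
        {g: math.log(efficiencies[g]) / math.log(2.0) for g in matrix.genes}
    )
    values = matrix.values.mul(factors, axis=0)
    return ExpressionMatrix(values=values, scale=Scale.CQE, groups=matrix.groups)


def to_relative_quantity(
    matrix: ExpressionMatrix, base: float = 2.0
) -> ExpressionMatrix:
    """Convert cycles to relative quantities ``Q = base**(minCq - Cq)`` per gene.

    The per-gene maximum is exactly 1 (the sample with the lowest Cq, i.e.
    the highest expression).
    """
    if matrix.scale not in (Scale.CQ, Scale.CQE):
        raise DomainError("to_relative_quantity expects a cycle-scale matrix")
    if not base > 1:
        raise DomainError(f"base must be > 1, got {base}")
    if matrix.values.empty:
        raise DomainError("empty matrix")
    mins = matrix.values.min(axis=1)
    values = np.power(float(base), matrix.values.rsub(mins, axis=0).astype(float))
    return ExpressionMatrix(values=values, scale=Scale.QUANTITY, groups=matrix.groups)


def _tukey_summary(gene: str, x: np.ndarray) -> DistributionSummary:
    x = np.sort(np.asarray(x, dtype=float))
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(x[(x < lo_fence) | (x > hi_fence)])
    # whiskers span the non-outliers but never retreat inside the box
    # (interpolated quartiles can exceed every non-outlier value)
    return DistributionSummary(
        gene=gene,
        n=len(x),
        mean=float(np.mean(x)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(min(inside.min(), q1)),
        whisker_high=float(max(inside.max(), q3)),
        outliers=outliers,
    )


def summarize_distribution(matrix: ExpressionMatrix) -> dict[str, DistributionSummary]:
    """Boxplot-style summary per gene: quartiles, whiskers, Tukey outliers.

    Quartiles use linear interpolation; outliers fall outside the
    1.5 x IQR fences; whiskers are the min/max of the non-outliers.
    With n=1 all statistics collapse to the single value.
    """
    return {
        g: _tukey_summary(g, matrix.values.loc[g].to_numpy()) for g in matrix.genes
    }
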