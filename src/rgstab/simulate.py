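"""Synthetic qPCR Cq tables and RNA-seq count matrices.

Generative models match the assumptions of the downstream analyses:

- Cq noise is Gaussian on the cycle (log) scale, decomposed into sample,
  gene x sample, and technical-replicate components, with optional
  per-gene group effects (planted instability);
- counts are negative-binomial with per-group fold changes and per-sample
  library-size factors, emitted together with a ground-truth
  differential-expression table so that filters can be tested exactly.

Every spec carries a mandatory seed; identical spec + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .qpcr import CqTable
from .screen import CountMatrix, DETable

__all__ = [
    "CqGeneSpec",
    "CqSimSpec",
    "CountGeneSpec",
    "CountSimSpec",
    "simulate_cq",
    "simulate_counts",
    "study_like_cq_spec",
    "study_like_count_spec",
]

DEFAULT_GENES = ("ADF2", "CYB5", "iPGAM", "SCL13", "TRXL3-3", "VHA-H")


@dataclass
class CqGeneSpec:
    name: str
    baseline_cq: float
    efficiency: float = 2.0
    group_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0


@dataclass
class CqSimSpec:
    """Generative spec for a qPCR Cq table.

    Cq(gene g, sample s in group j, technical replicate r) =
    baseline_g + delta_g(j) + u_s + eps_gs + eta_gsr with independent
    Gaussian u, eps, eta.
    """

    genes: list[CqGeneSpec]
    groups: list[tuple[str, int]]  # (label, n biological samples)
    sample_effect_sd: float = 0.0
    replicate_sd: float = 0.0
    n_replicates: int = 2
    seed: int = 0
    experiment_id: str = "sim"

    def validate(self) -> None:
        if not self.genes:
            raise DomainError("at least one gene required")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise DomainError("every group needs >= 1 sample")
        for g in self.genes:
            if not (1 < g.efficiency <= 2):
                raise DomainError(f"gene {g.name}: efficiency must be in (1, 2]")
            if g.noise_sd < 0:
                raise DomainError(f"gene {g.name}: noise_sd must be >= 0")
            if not (0 < g.baseline_cq):
                raise DomainError(f"gene {g.name}: baseline_cq must be > 0")
            unknown = set(g.group_effects) - {lbl for lbl, _ in self.groups}
            if unknown:
                raise DomainError(f"gene {g.name}: unknown group(s) {sorted(unknown)}")
        if self.sample_effect_sd < 0 or self.replicate_sd < 0:
            raise DomainError("sample_effect_sd and replicate_sd must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")


@dataclass
class CountGeneSpec:
    name: str
    base_mean: float
    group_log2fc: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.05


@dataclass
class CountSimSpec:
    """Generative spec for a negative-binomial count matrix.

    Mean of gene g in sample s of group j is
    base_mean_g * 2**log2fc_g(j) * libsize_factor_s; the NB dispersion
    alpha gives variance mu + alpha * mu**2.
    """

    genes: list[CountGeneSpec]
    groups: list[tuple[str, int]]
    library_size_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0
    experiment_id: str = "sim"

    def validate(self) -> None:
        if not self.genes:
            raise DomainError("at least one gene required")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise DomainError("every group needs >= 1 sample")
        for g in self.genes:
            if g.base_mean <= 0:
                raise DomainError(f"gene {g.name}: base_mean must be > 0")
            if g.dispersion <= 0:
                raise DomainError(f"gene {g.name}: dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise DomainError("library_size_range must be positive with low <= high")


def simulate_cq(spec: CqSimSpec) -> CqTable:
    """Draw a long-format Cq table from the additive Gaussian model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = [
        (f"{lbl}_{i + 1}", lbl) for lbl, n in spec.groups for i in range(n)
    ]
    u = {sid: rng.normal(0.0, spec.sample_effect_sd) for sid, _ in samples}
    rows = []
    for gene in spec.genes:
        for sid, lbl in samples:
            eps = rng.normal(0.0, gene.noise_sd)
            level = gene.baseline_cq + gene.group_effects.get(lbl, 0.0) + u[sid] + eps
            for r in range(1, spec.n_replicates + 1):
                eta = rng.normal(0.0, spec.replicate_sd)
                rows.append(
                    {
                        "sample_id": sid,
                        "group": lbl,
                        "gene": gene.name,
                        "replicate": r,
                        "cq": level + eta,
                        "efficiency": gene.efficiency,
                    }
                )
    return CqTable(data=pd.DataFrame(rows), experiment_id=spec.experiment_id)


def simulate_counts(spec: CountSimSpec) -> tuple[CountMatrix, DETable]:
    """Draw an NB count matrix plus its ground-truth DE table.

    The truth table reports, per gene, the planted log2 fold change
    (largest-magnitude group effect; 0 when none), an idealised FDR
    (0 when the gene has a planted |log2FC| > 1, else 1 — so the
    DE-stability filter recovers exactly the planted-stable genes), and
    the expected mean count.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = [
        (f"{lbl}_{i + 1}", lbl) for lbl, n in spec.groups for i in range(n)
    ]
    lo, hi = spec.library_size_range
    libfac = {sid: rng.uniform(lo, hi) for sid, _ in samples}
    counts = np.zeros((len(spec.genes), len(samples)), dtype=np.int64)
    for gi, gene in enumerate(spec.genes):
        size = 1.0 / gene.dispersion  # NB shape parameter
        for si, (sid, lbl) in enumerate(samples):
            mu = gene.base_mean * 2.0 ** gene.group_log2fc.get(lbl, 0.0) * libfac[sid]
            p = size / (size + mu)
            counts[gi, si] = rng.negative_binomial(size, p)
    matrix = pd.DataFrame(
        counts, index=[g.name for g in spec.genes], columns=[s for s, _ in samples]
    )
    cm = CountMatrix(
        counts=matrix,
        groups={sid: lbl for sid, lbl in samples},
        experiment_id=spec.experiment_id,
    )

    truth_rows = []
    for gene in spec.genes:
        effects = list(gene.group_log2fc.values())
        lfc = max(effects, key=abs) if effects else 0.0
        truth_rows.append(
            {
                "gene": gene.name,
                "log2fc": lfc,
                "fdr": 0.0 if abs(lfc) > 1.0 else 1.0,
                "mean_count": gene.base_mean,
            }
        )
    return cm, DETable(pd.DataFrame(truth_rows))


def study_like_cq_spec(
    seed: int = 0,
    unstable_gene: str | None = None,
    effect: float = 0.0,
    noise_sd: float = 0.3,
) -> CqSimSpec:
    """A study-shaped default: six genes with baselines spread over 31-38
    cycles, three irrigation-style groups of three biological samples, and
    two technical replicates. Optionally plant a group effect on one gene."""
    baselines = dict(zip(DEFAULT_GENES, (31.5, 32.0, 37.5, 37.0, 34.5, 33.0)))
    efficiencies = dict(zip(DEFAULT_GENES, (1.95, 1.88, 1.92, 1.80, 1.90, 1.97)))
    groups = [("C", 3), ("DI-1", 3), ("DI-2", 3)]
    genes = []
    for name in DEFAULT_GENES:
        effects = {}
        if name == unstable_gene:
            effects = {"DI-1": effect / 2.0, "DI-2": effect}
        genes.append(
            CqGeneSpec(
                name=name,
                baseline_cq=baselines[name],
                efficiency=efficiencies[name],
                group_effects=effects,
                noise_sd=noise_sd,
            )
        )
    return CqSimSpec(
        genes=genes,
        groups=groups,
        sample_effect_sd=0.2,
        replicate_sd=0.1,
        n_replicates=2,
        seed=seed,
        experiment_id="study_like",
    )


def study_like_count_spec(seed: int = 0) -> CountSimSpec:
    """Counts for the six study genes plus three deliberately unstable
    housekeeping-style genes, two groups of three samples each."""
    genes = [
        CountGeneSpec(name=n, base_mean=m)
        for n, m in zip(DEFAULT_GENES, (800, 1200, 300, 250, 500, 650))
    ]
    genes += [
        CountGeneSpec(name="ACT", base_mean=5000, group_log2fc={"red": 2.0}),
        CountGeneSpec(name="GAPDH-2C", base_mean=4000, group_log2fc={"red": -1.8}),
        CountGeneSpec(name="UPL6", base_mean=150, group_log2fc={"red": 2.5}),
    ]
    return CountSimSpec(
        genes=genes,
        groups=[("green", 3), ("red", 3)],
        library_size_range=(0.8, 1.2),
        seed=seed,
        experiment_id="study_like",
    )
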