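"""Core in-memory containers shared across the pipeline.

Dosage matrices are stored sample x variant as floats with NaN for missing
calls; count matrices are gene x sample integer arrays. Containers are thin
dataclasses around numpy arrays so every module can stay vector-oriented;
``to_frame`` methods give labelled pandas views for display and I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantMeta",
    "GenotypeMatrix",
    "CountMatrix",
    "SampleSheet",
    "SizeFactors",
    "NormalizedExpression",
    "EqtlRecord",
    "GroupComparison",
    "CoexprRecord",
]


@dataclass(frozen=True)
class VariantMeta:
    """A biallelic variant: identifier, 1-based position and alleles."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages (0/1/2, NaN = missing) for samples x variants.

    Dosage counts ALT alleles as read from the file, not minor alleles:
    the coding is then reproducible from the input alone, and association
    direction is reported explicitly downstream.
    """

    samples: list[str]
    variants: list[VariantMeta]
    dosage: np.ndarray  # float, shape (n_samples, n_variants), NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique within a GenotypeMatrix")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosage[~ok][0]
            raise ValueError(f"dosage values must be in {{0,1,2,NaN}}; found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.samples, columns=self.variant_ids())

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(list(samples), list(self.variants), self.dosage[idx, :])


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples, non-negative integers."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray  # int, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        self.counts = counts.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


@dataclass
class SampleSheet:
    """Case/control status per sample."""

    samples: list[str]
    status: list[Literal["case", "control"]]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.status):
            raise ValueError("samples and status must have equal length")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        bad = sorted({s for s in self.status if s not in ("case", "control")})
        if bad:
            raise ValueError(f"status must be 'case' or 'control'; found {bad}")

    def status_of(self, sample: str) -> str:
        return self.status[self.samples.index(sample)]

    def group(self, which: str) -> list[str]:
        return [s for s, st in zip(self.samples, self.status) if st == which]


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scaling constants (all > 0)."""

    samples: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.samples),):
            raise ValueError("one size factor per sample required")
        if not (self.factors > 0).all():
            raise ValueError("size factors must be strictly positive")


@dataclass
class NormalizedExpression:
    """Counts divided by their sample's size factor; keeps provenance."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # float, genes x samples
    size_factors: SizeFactors

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match genes x samples")

    def gene(self, gene_id: str) -> np.ndarray:
        try:
            i = self.genes.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present") from None
        return self.values[i, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class EqtlRecord:
    """Outcome of one association test at one variant.

    ``statistic`` is the Wald t for the linear model and the tie-corrected
    trend statistic T for the directional test. ``group_summary`` holds, per
    dosage group, (n, mean, sd) of normalized expression, plus the pairwise
    probabilistic indices for the directional test.
    """

    variant: VariantMeta
    method: Literal["linear", "directional"]
    statistic: float
    direction: Literal["increasing", "decreasing", "none"]
    p: float
    p_adjusted: float = float("nan")
    group_summary: dict = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0,1], got {self.p}")


@dataclass
class GroupComparison:
    """Case/control summary of one gene's normalized expression."""

    test: str
    statistic: float
    p: float
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    sd_case: float
    sd_control: float


@dataclass
class CoexprRecord:
    """Pearson co-expression of one gene with the target gene."""

    gene: str
    r: float
    n: int
    p: float
    p_bh: float = float("nan")
    p_bonferroni: float = float("nan")
    klass: Literal["positive", "negative", "none"] = "none"
    constant: bool = False  # r undefined because one vector was constant
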