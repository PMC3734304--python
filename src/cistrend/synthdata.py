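"""Self-contained synthetic cohorts with the statistical shape the analysis
assumes.

Defaults reproduce the study design the pipeline targets: 84 cases + 15
controls, 468 variants drawn uniformly over a 2 Mb window (+/- 1 Mb around
the anchor), Hardy-Weinberg genotypes at configurable minor-allele
frequencies, and negative-binomial read counts with per-sample depth factors.
cis-eQTL signal is planted as an additive shift beta on the log-mean per alt
allele; a multiplicative case effect (default 0.7, i.e. a 30% drop) acts on
the target gene's mean in cases only. Variants are independent by default; a
Gaussian-copula block mode adds LD-like correlation.

Counts are NB(mean mu, dispersion phi) with variance mu + phi * mu^2, the
parameterization under which median-of-ratios normalization is the natural
first step. Everything is reproducible from (config, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._types import CountMatrix, GenotypeMatrix, SampleSheet, VariantMeta

__all__ = ["PlantedEffect", "SimConfig", "simulate_genotypes",
           "simulate_expression", "simulate_dataset"]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedEffect:
    """A cis-eQTL effect: additive shift on log-mean per alt allele."""

    variant_index: int
    beta: float
    gene: str | None = None  # None = the target gene


@dataclass
class SimConfig:
    n_cases: int = 84
    n_controls: int = 15
    n_variants: int = 468
    chrom: str = "13"
    anchor_pos: int = 50_200_000
    window_span_bp: int = 2_000_000  # total span; variants within +/- span/2
    maf: tuple[float, float] | np.ndarray = (0.05, 0.5)
    n_genes: int = 200
    target_gene: str = "TARGET"
    nb_mean_range: tuple[float, float] = (50.0, 1000.0)  # log-uniform baseline
    nb_dispersion: float = 0.1
    depth_sigma: float = 0.25  # per-sample depth ~ lognormal(0, sigma)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    case_effect: float = 0.7
    ld_block_size: int = 0   # 0 = independent variants
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls < 1:
            raise ValueError("need at least one sample")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")
        if not (0 < self.case_effect):
            raise ValueError("case_effect must be > 0")
        maf = np.asarray(self.maf, dtype=float)
        if not ((maf > 0) & (maf <= 0.5)).all():
            raise ValueError("maf must lie in (0, 0.5]")
        for eff in self.planted_effects:
            if not (0 <= eff.variant_index < self.n_variants):
                raise ValueError(
                    f"planted variant index {eff.variant_index} out of range"
                )

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]

    def gene_ids(self) -> list[str]:
        other = [f"G{i:04d}" for i in range(self.n_genes - 1)]
        return [self.target_gene] + other

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def _variant_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    maf = np.asarray(cfg.maf, dtype=float)
    if maf.ndim == 0:
        return np.full(cfg.n_variants, float(maf))
    if maf.ndim == 1 and len(maf) == cfg.n_variants:
        return maf
    if maf.shape == (2,):
        return rng.uniform(maf[0], maf[1], size=cfg.n_variants)
    raise ValueError("maf must be a scalar, a (lo, hi) range, or per-variant")


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """HWE genotypes: dosage_ij ~ Binomial(2, maf_j), independent samples.

    Positions are uniform over the window, sorted and de-duplicated; with
    ``ld_block_size`` > 1 allele draws within a block share a Gaussian copula
    with correlation ``ld_rho``.
    """
    rng = cfg._rng(0)
    mafs = _variant_mafs(cfg, rng)
    half = cfg.window_span_bp // 2
    lo, hi = cfg.anchor_pos - half, cfg.anchor_pos + half
    positions = np.sort(
        rng.choice(np.arange(lo, hi + 1), size=cfg.n_variants, replace=False)
    )
    n = cfg.n_samples
    if cfg.ld_block_size > 1 and cfg.ld_rho != 0.0:
        dosage = np.zeros((n, cfg.n_variants))
        for start in range(0, cfg.n_variants, cfg.ld_block_size):
            idx = np.arange(start, min(start + cfg.ld_block_size, cfg.n_variants))
            k = len(idx)
            cov = np.full((k, k), cfg.ld_rho) + (1 - cfg.ld_rho) * np.eye(k)
            chol = np.linalg.cholesky(cov)
            for copy in range(2):  # two correlated allele draws per sample
                z = rng.standard_normal((n, k)) @ chol.T
                alleles = (stats.norm.cdf(z) < mafs[idx]).astype(float)
                dosage[:, idx] += alleles
    else:
        dosage = rng.binomial(2, mafs[np.newaxis, :], size=(n, cfg.n_variants))
    ref_idx = rng.integers(0, 4, size=cfg.n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_variants)) % 4
    variants = [
        VariantMeta(
            id=f"var{j:04d}", chrom=cfg.chrom, pos=int(positions[j]),
            ref=str(_ALLELES[ref_idx[j]]), alt=str(_ALLELES[alt_idx[j]]),
        )
        for j in range(cfg.n_variants)
    ]
    return GenotypeMatrix(cfg.sample_ids(), variants, dosage.astype(float))


def simulate_expression(
    cfg: SimConfig, g: GenotypeMatrix
) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """NB counts with planted cis effects; returns (counts, sheet, truth).

    counts_ij ~ NB(mean = d_j * mu_i * exp(sum beta * dosage_j) * case_shift,
    dispersion phi), with d_j the sample depth factor and the case shift
    applied to the target gene in cases only. The truth table lists every
    planted (variant, gene, beta) plus the case effect.
    """
    if g.n_samples != cfg.n_samples:
        raise ValueError("genotype matrix does not match the configured cohort")
    rng = cfg._rng(1)
    genes = cfg.gene_ids()
    gene_index = {gid: i for i, gid in enumerate(genes)}
    lo, hi = cfg.nb_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    depth = rng.lognormal(mean=0.0, sigma=cfg.depth_sigma, size=cfg.n_samples)
    status = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    is_case = np.array([s == "case" for s in status], dtype=float)

    log_shift = np.zeros((cfg.n_genes, cfg.n_samples))
    truth_rows = []
    for eff in cfg.planted_effects:
        gene = eff.gene or cfg.target_gene
        gi = gene_index[gene]
        dos = np.nan_to_num(g.dosage[:, eff.variant_index])
        log_shift[gi, :] += eff.beta * dos
        truth_rows.append(
            {"kind": "eqtl", "variant": g.variants[eff.variant_index].id,
             "gene": gene, "beta": eff.beta}
        )
    truth_rows.append(
        {"kind": "case_effect", "variant": "NA", "gene": cfg.target_gene,
         "beta": cfg.case_effect}
    )

    mean = depth[np.newaxis, :] * mu[:, np.newaxis] * np.exp(log_shift)
    ti = gene_index[cfg.target_gene]
    mean[ti, :] *= np.where(is_case == 1.0, cfg.case_effect, 1.0)
    # NB(mean mu, dispersion phi): var = mu + phi mu^2; numpy wants (r, p)
    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p)
    return (
        CountMatrix(genes, g.samples, counts.astype(np.int64)),
        SampleSheet(list(g.samples), status),
        pd.DataFrame(truth_rows, columns=["kind", "variant", "gene", "beta"]),
    )


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, CountMatrix, SampleSheet, pd.DataFrame]:
    """Genotypes + expression + sheet + truth in one reproducible call."""
    g = simulate_genotypes(cfg)
    counts, sheet, truth = simulate_expression(cfg, g)
    return g, counts, sheet, truth
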