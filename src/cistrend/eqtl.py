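"""Cis-window selection and the two per-variant association tests.

Two tests run at every variant in the cis window:

* a linear regression of normalized expression on additive alt-allele dosage
  (Wald t on the slope, two-sided p from the t distribution with n - 2 df) —
  the classic PLINK-style eQTL model;
* a directional trend test for stochastic ordering of the expression
  distributions across the ordered genotype groups. Its statistic is the
  tie-corrected Jonckheere-Terpstra sum of pairwise Mann-Whitney counts,

      T = sum_{k<l} sum_{i in group k, j in group l}
              [ 1(x_i < x_j) + 1/2 * 1(x_i = x_j) ],

  so U_kl / (n_k * n_l) estimates the probabilistic index
  P(X_k < X_l) + 1/2 P(X_k = X_l) for each ordered group pair. Inference is
  by permutation of expression across samples with group sizes fixed: exact
  full enumeration when the number of distinct index assignments is small,
  otherwise Monte-Carlo with the add-one estimator (b + 1)/(B + 1). The
  reported two-sided p doubles the smaller one-sided tail (capped at 1).

Randomness is governed by a single master seed; each variant derives a child
seed from (seed, CRC32 of its id) so per-variant results do not depend on
scan order.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._types import EqtlRecord, GenotypeMatrix, NormalizedExpression, VariantMeta

logger = logging.getLogger(__name__)

__all__ = [
    "CisWindow",
    "GenotypeGroups",
    "PermutationPlan",
    "UntestableVariant",
    "ScanResult",
    "select_cis_variants",
    "group_by_genotype",
    "linear_eqtl",
    "jt_statistic",
    "pairwise_probabilistic_indices",
    "directional_test",
    "run_scan",
]

_EPS = 1e-9  # tolerance when comparing permuted T values (multiples of 0.5)


class UntestableVariant(ValueError):
    """Raised when a variant cannot support the requested test."""


@dataclass(frozen=True)
class CisWindow:
    """A symmetric window of ``width`` bp around a 1-based anchor position."""

    chrom: str
    pos: int
    width: int

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("window width must be >= 0")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and abs(pos - self.pos) <= self.width


@dataclass
class GenotypeGroups:
    """Expression values split by dosage group, ordered by dosage."""

    levels: list[int]                # observed dosage levels, ascending
    values: list[np.ndarray]         # one array per level, sample-aligned

    @property
    def sizes(self) -> list[int]:
        return [len(v) for v in self.values]

    @property
    def n(self) -> int:
        return sum(self.sizes)

    @property
    def total_cross_pairs(self) -> int:
        sz = self.sizes
        return sum(a * b for i, a in enumerate(sz) for b in sz[i + 1:])

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled values and their integer group index (0..K-1)."""
        x = np.concatenate(self.values)
        g = np.concatenate(
            [np.full(len(v), k, dtype=np.int64) for k, v in enumerate(self.values)]
        )
        return x, g

    def summary(self) -> dict:
        return {
            int(level): {
                "n": int(len(v)),
                "mean": float(np.mean(v)) if len(v) else float("nan"),
                "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
            }
            for level, v in zip(self.levels, self.values)
        }


@dataclass(frozen=True)
class PermutationPlan:
    """How permutation p-values are computed.

    Full enumeration is used when the number of distinct assignments of
    samples to groups (the multinomial coefficient) is at most
    ``enumeration_cap``; otherwise ``B`` Monte-Carlo permutations with the
    add-one estimator. ``side`` selects the reported tail: ``two-sided``
    doubles the smaller one-sided p.
    """

    B: int = 10_000
    seed: int = 0
    enumeration_cap: int = 200_000
    side: str = "two-sided"  # "two-sided" | "increasing" | "decreasing"

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("Monte-Carlo permutation count B must be >= 100")
        if self.side not in ("two-sided", "increasing", "decreasing"):
            raise ValueError(f"unknown side {self.side!r}")

    def child_rng(self, variant_id: str) -> np.random.Generator:
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(zlib.crc32(variant_id.encode()),)
        )
        return np.random.default_rng(ss)


@dataclass
class ScanResult:
    """Both per-method record lists plus bookkeeping for skipped variants."""

    linear: list[EqtlRecord]
    directional: list[EqtlRecord]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def select_cis_variants(g: GenotypeMatrix, w: CisWindow) -> GenotypeMatrix:
    """Keep variants on the anchor chromosome within +/- width bp, inclusive
    at both boundaries; input order preserved."""
    keep = [j for j, v in enumerate(g.variants) if w.contains(v.chrom, v.pos)]
    if not keep:
        raise ValueError(
            f"no variants within {w.chrom}:{w.pos} +/- {w.width} bp"
        )
    return GenotypeMatrix(
        list(g.samples), [g.variants[j] for j in keep], g.dosage[:, keep]
    )


def group_by_genotype(
    dosages: np.ndarray, expr: np.ndarray, min_group_n: int = 2
) -> GenotypeGroups:
    """Split expression by dosage group, dropping missing-dosage samples.

    Raises UntestableVariant when fewer than two groups reach
    ``min_group_n`` samples (monomorphic or near-monomorphic variants).
    """
    dosages = np.asarray(dosages, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if dosages.shape != expr.shape:
        raise ValueError("dosage and expression vectors must be sample-aligned")
    ok = ~np.isnan(dosages)
    dosages, expr = dosages[ok], expr[ok]
    levels = sorted(set(int(d) for d in dosages))
    values = [expr[dosages == lv] for lv in levels]
    usable = sum(len(v) >= min_group_n for v in values)
    if usable < 2:
        raise UntestableVariant(
            f"fewer than 2 genotype groups with >= {min_group_n} samples "
            f"(group sizes: {[len(v) for v in values]})"
        )
    return GenotypeGroups(levels, values)


def linear_eqtl(
    variant: VariantMeta, dosages: np.ndarray, expr: np.ndarray
) -> EqtlRecord:
    """OLS of expression on additive dosage; Wald t for the slope.

    Missing dosages are dropped (complete case). Requires >= 3 non-missing
    samples and >= 2 distinct dosage values. A perfect fit with nonzero slope
    reports p = 0 with the degeneracy flag set.
    """
    dosages = np.asarray(dosages, dtype=float)
    expr = np.asarray(expr, dtype=float)
    ok = ~np.isnan(dosages)
    x, y = dosages[ok], expr[ok]
    n = len(x)
    if n < 3:
        raise UntestableVariant(f"{variant.id}: need >= 3 non-missing samples")
    if len(np.unique(x)) < 2:
        raise UntestableVariant(f"{variant.id}: all dosages equal")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sse = float(resid @ resid)
    df = n - 2
    groups = None
    try:
        groups = group_by_genotype(x, y, min_group_n=1)
    except UntestableVariant:  # pragma: no cover - guarded above
        pass
    summary = groups.summary() if groups is not None else {}
    if sse <= _EPS * max(1.0, float(yc @ yc)):
        # zero residual variance: infinite t, degenerate
        direction = (
            "increasing" if slope > 0 else "decreasing" if slope < 0 else "none"
        )
        return EqtlRecord(
            variant=variant,
            method="linear",
            statistic=math.inf if slope > 0 else -math.inf if slope < 0 else 0.0,
            direction=direction,
            p=0.0 if slope != 0 else 1.0,
            group_summary={"slope": slope, "groups": summary, "n": n},
            degenerate=True,
        )
    se = math.sqrt(sse / df / sxx)
    t = slope / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return EqtlRecord(
        variant=variant,
        method="linear",
        statistic=t,
        direction="increasing" if slope > 0 else "decreasing" if slope < 0 else "none",
        p=min(p, 1.0),
        group_summary={"slope": slope, "se": se, "df": df, "groups": summary, "n": n},
    )


def _comparison_matrix(x: np.ndarray) -> np.ndarray:
    """A[i, j] = 1(x_i < x_j) + 0.5 * 1(x_i = x_j) for the pooled sample."""
    lt = (x[:, None] < x[None, :]).astype(float)
    eq = (x[:, None] == x[None, :]).astype(float)
    return lt + 0.5 * eq


def _t_from_labels(A: np.ndarray, g: np.ndarray, n_levels: int) -> float:
    t = 0.0
    for k in range(n_levels):
        mk = g == k
        for l in range(k + 1, n_levels):
            t += float(A[np.ix_(mk, g == l)].sum())
    return t


def jt_statistic(groups: GenotypeGroups) -> float:
    """Tie-corrected Jonckheere-Terpstra trend statistic over ordered groups."""
    if len(groups.values) < 2:
        raise UntestableVariant("trend statistic needs >= 2 groups")
    x, g = groups.pooled()
    return _t_from_labels(_comparison_matrix(x), g, len(groups.values))


def pairwise_probabilistic_indices(groups: GenotypeGroups) -> dict:
    """U_kl / (n_k * n_l) for every ordered pair of dosage levels k < l."""
    A = _comparison_matrix(groups.pooled()[0])
    sizes = groups.sizes
    offs = np.concatenate([[0], np.cumsum(sizes)])
    out = {}
    for k in range(len(sizes)):
        for l in range(k + 1, len(sizes)):
            ik = slice(offs[k], offs[k + 1])
            il = slice(offs[l], offs[l + 1])
            u = float(A[ik, il].sum())
            out[(groups.levels[k], groups.levels[l])] = u / (sizes[k] * sizes[l])
    return out


def _n_arrangements(sizes: list[int]) -> int:
    n = sum(sizes)
    c = math.factorial(n)
    for s in sizes:
        c //= math.factorial(s)
    return c


def _enumerate_t(x: np.ndarray, sizes: list[int]) -> np.ndarray:
    """T for every distinct assignment of pooled indices to groups."""
    A = _comparison_matrix(x)
    n = len(x)
    n_levels = len(sizes)
    ts = []
    labels = np.empty(n, dtype=np.int64)

    def rec(remaining: tuple[int, ...], level: int) -> None:
        if level == n_levels - 1:
            labels[list(remaining)] = level
            ts.append(_t_from_labels(A, labels, n_levels))
            return
        for chosen in itertools.combinations(remaining, sizes[level]):
            labels[list(chosen)] = level
            rest = tuple(i for i in remaining if i not in chosen)
            rec(rest, level + 1)

    rec(tuple(range(n)), 0)
    return np.asarray(ts)


def _montecarlo_t(
    x: np.ndarray, g: np.ndarray, n_levels: int, B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """T under B random permutations of group labels (vectorised).

    Permuting expression across samples with group sizes fixed is equivalent
    to permuting the labels; each pair contribution is a masked bilinear form
    in the comparison matrix, evaluated as one matmul per level pair.
    """
    A = _comparison_matrix(x)
    perms = rng.permuted(np.tile(g, (B, 1)), axis=1)
    t = np.zeros(B)
    for k in range(n_levels):
        mk = (perms == k).astype(float)
        for l in range(k + 1, n_levels):
            ml = (perms == l).astype(float)
            t += ((mk @ A) * ml).sum(axis=1)
    return t


def directional_test(
    variant: VariantMeta,
    groups: GenotypeGroups,
    plan: PermutationPlan,
) -> EqtlRecord:
    """Permutation inference for the trend statistic.

    One-sided tails are p_inc = P(T_perm >= T_obs) and
    p_dec = P(T_perm <= T_obs); full enumeration makes them exact, Monte-Carlo
    uses (b + 1)/(B + 1). The reported p follows ``plan.side``; the default
    two-sided p is min(1, 2 * min(p_inc, p_dec)) with direction the smaller
    tail.
    """
    x, g = groups.pooled()
    n_levels = len(groups.values)
    t_obs = jt_statistic(groups)
    n_arr = _n_arrangements(groups.sizes)
    if n_arr <= plan.enumeration_cap:
        ts = _enumerate_t(x, groups.sizes)
        p_inc = float((ts >= t_obs - _EPS).sum()) / len(ts)
        p_dec = float((ts <= t_obs + _EPS).sum()) / len(ts)
        mode = "enumeration"
        b = len(ts)
    else:
        rng = plan.child_rng(variant.id)
        ts = _montecarlo_t(x, g, n_levels, plan.B, rng)
        p_inc = (float((ts >= t_obs - _EPS).sum()) + 1.0) / (plan.B + 1.0)
        p_dec = (float((ts <= t_obs + _EPS).sum()) + 1.0) / (plan.B + 1.0)
        mode = "monte_carlo"
        b = plan.B
    if plan.side == "increasing":
        p, direction = p_inc, "increasing"
    elif plan.side == "decreasing":
        p, direction = p_dec, "decreasing"
    else:
        p = min(1.0, 2.0 * min(p_inc, p_dec))
        if p_inc < p_dec:
            direction = "increasing"
        elif p_dec < p_inc:
            direction = "decreasing"
        else:
            direction = "none"
    summary = {
        "groups": groups.summary(),
        "probabilistic_index": {
            f"{k}<{l}": v for (k, l), v in pairwise_probabilistic_indices(groups).items()
        },
        "p_inc": p_inc,
        "p_dec": p_dec,
        "mode": mode,
        "B": b,
        "n": groups.n,
    }
    return EqtlRecord(
        variant=variant,
        method="directional",
        statistic=t_obs,
        direction=direction,
        p=p,
        group_summary=summary,
    )


def run_scan(
    g: GenotypeMatrix,
    expr: NormalizedExpression,
    gene_id: str,
    window: CisWindow,
    plan: PermutationPlan,
    sample_subset: list[str] | None = None,
    min_group_n: int = 2,
    log_expression: bool = False,
) -> ScanResult:
    """Run both tests at every cis variant.

    Samples are intersected between genotype and expression (ordered as in
    the expression matrix) and optionally restricted to ``sample_subset``
    (e.g. cases only). ``log_expression`` runs the linear model on
    log(1 + normalized) values; the rank-based directional test is unchanged
    by any monotone transform and always uses the normalized scale.
    """
    if gene_id not in expr.genes:
        raise ValueError(f"target gene {gene_id!r} not in expression matrix")
    shared = [s for s in expr.samples if s in set(g.samples)]
    if sample_subset is not None:
        subset = set(sample_subset)
        shared = [s for s in shared if s in subset]
    if not shared:
        raise ValueError("no samples shared between genotype and expression data")
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= 10 for the scan"
        )
    if len(shared) < 30:
        logger.warning("run_scan: only %d shared samples (< 30)", len(shared))

    cis = select_cis_variants(g, window)
    cis = cis.subset_samples(shared)
    y = expr.gene(gene_id)[[expr.samples.index(s) for s in shared]]
    y_lin = np.log1p(y) if log_expression else y

    linear: list[EqtlRecord] = []
    directional: list[EqtlRecord] = []
    skipped: list[tuple[str, str]] = []
    for j, v in enumerate(cis.variants):
        d = cis.dosage[:, j]
        try:
            groups = group_by_genotype(d, y, min_group_n=min_group_n)
        except UntestableVariant as exc:
            skipped.append((v.id, str(exc)))
            logger.info("run_scan: skipping %s (%s)", v.id, exc)
            continue
        try:
            linear.append(linear_eqtl(v, d, y_lin))
            directional.append(directional_test(v, groups, plan))
        except UntestableVariant as exc:
            skipped.append((v.id, str(exc)))
            logger.info("run_scan: skipping %s (%s)", v.id, exc)
    logger.info(
        "run_scan: %d variants tested, %d skipped", len(linear), len(skipped)
    )
    return ScanResult(linear=linear, directional=directional, skipped=skipped)
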