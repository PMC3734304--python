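"""Case/control expression comparison and the thresholded co-expression screen.

``compare_groups`` contrasts the target gene's normalized expression between
cases and controls with either the Wilcoxon rank-sum test (default; exact
when sample sizes allow, robust for a 15-control arm) or Welch's t.

``coexpression_screen`` correlates the target gene with every other gene
(Pearson, complete pairs), derives two-sided p-values from
t = r * sqrt((n - 2)/(1 - r^2)) with n - 2 df (optionally by permutation for
small n), applies BH and Bonferroni corrections over the screened family, and
classes each gene as positively/negatively co-expressed when |r| exceeds the
correlation threshold AND p beats the significance threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._types import CoexprRecord, GroupComparison, NormalizedExpression, SampleSheet
from .multiplicity import bh_adjust, bonferroni_adjust

__all__ = ["compare_groups", "coexpression_screen"]


def compare_groups(
    expr: np.ndarray,
    samples: list[str],
    sheet: SampleSheet,
    test: str = "wilcoxon",
) -> GroupComparison:
    """Two-sided case vs control comparison of one gene's expression.

    ``expr`` is sample-aligned with ``samples``; samples absent from the
    sheet are ignored. Both groups need n >= 2.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape != (len(samples),):
        raise ValueError("expression vector must be sample-aligned")
    status = dict(zip(sheet.samples, sheet.status))
    cases = np.array([e for e, s in zip(expr, samples) if status.get(s) == "case"])
    controls = np.array(
        [e for e, s in zip(expr, samples) if status.get(s) == "control"]
    )
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError(
            f"both groups need n >= 2 (cases: {len(cases)}, "
            f"controls: {len(controls)})"
        )
    if test == "wilcoxon":
        res = stats.mannwhitneyu(cases, controls, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "welch_t":
        res = stats.ttest_ind(cases, controls, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 'welch_t'")
    return GroupComparison(
        test=test,
        statistic=stat,
        p=min(p, 1.0),
        n_case=len(cases),
        n_control=len(controls),
        mean_case=float(cases.mean()),
        mean_control=float(controls.mean()),
        sd_case=float(cases.std(ddof=1)),
        sd_control=float(controls.std(ddof=1)),
    )


def _pearson_p_permutation(
    x: np.ndarray, y: np.ndarray, r_obs: float, n_perm: int,
    rng: np.random.Generator,
) -> float:
    rs = np.empty(n_perm)
    for b in range(n_perm):
        rs[b] = np.corrcoef(x, rng.permutation(y))[0, 1]
    return (float((np.abs(rs) >= abs(r_obs) - 1e-12).sum()) + 1.0) / (n_perm + 1.0)


def coexpression_screen(
    expr: NormalizedExpression,
    target_gene: str,
    r_min: float = 0.30,
    p_max: float = 0.05,
    strict_r: float | None = None,
    permutation_p: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[CoexprRecord]:
    """Screen every gene for Pearson co-expression with ``target_gene``.

    Complete pairs only (both values finite), requiring n >= 3 per pair. The
    self-pair is excluded. Constant gene vectors yield an undefined r: the
    record is emitted with its ``constant`` flag set and excluded from
    classing and corrections. ``strict_r`` reports the stricter tier only
    (e.g. 0.50): records failing |r| > strict_r are still returned but
    classed 'none'. ``permutation_p`` swaps the t-transform p for a
    permutation p (small-n screens).
    """
    if target_gene not in expr.genes:
        raise ValueError(f"target gene {target_gene!r} not in matrix")
    others = [g for g in expr.genes if g != target_gene]
    if len(others) < 1:
        raise ValueError("co-expression screen needs at least 2 genes")
    x_all = expr.gene(target_gene)
    rng = np.random.default_rng(seed)
    records: list[CoexprRecord] = []
    for gene in others:
        y_all = expr.gene(gene)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        x, y = x_all[ok], y_all[ok]
        n = len(x)
        if n < 3:
            raise ValueError(f"gene {gene!r}: fewer than 3 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            records.append(
                CoexprRecord(gene=gene, r=float("nan"), n=n, p=float("nan"),
                             constant=True)
            )
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = max(-1.0, min(1.0, r))
        if permutation_p:
            p = _pearson_p_permutation(x, y, r, n_perm, rng)
        elif abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(stats.t.sf(abs(t), n - 2))
        records.append(CoexprRecord(gene=gene, r=r, n=n, p=min(p, 1.0)))

    defined = [rec for rec in records if not rec.constant]
    if defined:
        ps = np.array([rec.p for rec in defined])
        for rec, qb, qbf in zip(defined, bh_adjust(ps), bonferroni_adjust(ps)):
            rec.p_bh = float(qb)
            rec.p_bonferroni = float(qbf)
    r_cut = strict_r if strict_r is not None else r_min
    for rec in defined:
        if rec.r > r_cut and rec.p < p_max:
            rec.klass = "positive"
        elif rec.r < -r_cut and rec.p < p_max:
            rec.klass = "negative"
        else:
            rec.klass = "none"
    return records
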