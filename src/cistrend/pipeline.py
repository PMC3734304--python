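"""End-to-end, file-in/file-out orchestration of the pipeline stages.

Each stage reads and writes standard files so stages are independently
re-runnable: ``run_simulate`` materializes a synthetic cohort,
``run_eqtl`` runs normalization -> cis selection -> both scans -> BH per
method -> alpha scan per method and writes one result table per method plus a
JSON run manifest, ``run_compare_groups`` and ``run_coexpr`` cover the
case/control contrast and the co-expression screen. Configuration errors
raise ValueError and data problems propagate with their stage named; a fixed
seed makes every output byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._types import GenotypeMatrix, NormalizedExpression
from .assoc import compare_groups, coexpression_screen
from .eqtl import CisWindow, PermutationPlan, run_scan
from .io_formats import (
    read_counts,
    read_dosage_tsv,
    read_sample_sheet,
    read_vcf,
    write_alpha_scan,
    write_coexpr_table,
    write_counts,
    write_eqtl_table,
    write_sample_sheet,
    write_vcf,
)
from .multiplicity import alpha_scan, bh_adjust
from .normalize import normalize, size_factors
from .synthdata import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_eqtl", "run_compare_groups", "run_coexpr"]


def _write_manifest(path: Path, stage: str, payload: dict) -> None:
    manifest = {
        "stage": stage,
        "versions": {
            "cistrend": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        **payload,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_genotypes(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Dispatch on extension: .vcf via the VCF reader, anything else as the
    dosage TSV dialect."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return read_vcf(path, region=region)
    return read_dosage_tsv(path)


def run_simulate(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write a full synthetic cohort (VCF, counts TSV, sample sheet, truth
    table) plus a manifest; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, counts, sheet, truth = simulate_dataset(cfg)
    paths = {
        "genotypes": outdir / "genotypes.vcf",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(g, paths["genotypes"])
    write_counts(counts, paths["counts"])
    write_sample_sheet(sheet, paths["samples"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["maf"] = np.asarray(cfg.maf).tolist()
    _write_manifest(outdir / "manifest.json", "simulate", {
        "config": cfg_dict,
        "outputs": {k: str(v) for k, v in paths.items()},
        "seed": cfg.seed,
    })
    logger.info("simulate: wrote %d samples x %d variants to %s",
                cfg.n_samples, cfg.n_variants, outdir)
    return {k: str(v) for k, v in paths.items()}


def run_eqtl(
    genotypes: str | Path,
    counts: str | Path,
    gene: str,
    anchor_chrom: str,
    anchor_pos: int,
    outdir: str | Path,
    window_bp: int = 1_000_000,
    permutations: int = 10_000,
    enumeration_cap: int = 200_000,
    seed: int = 0,
    alpha_step: float = 0.001,
    min_group_n: int = 2,
    log_expression: bool = False,
    side: str = "two-sided",
    sample_subset: list[str] | None = None,
    truth: str | Path | None = None,
) -> dict:
    """Full cis-eQTL stage; writes linear.tsv, directional.tsv, per-method
    alpha-scan TSVs and a manifest. When a truth table is supplied, planted
    variants are marked in an extra ``planted`` column."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        g = read_genotypes(genotypes)
    except Exception as exc:
        raise type(exc)(f"[stage: read genotypes] {exc}") from exc
    try:
        cm = read_counts(counts)
    except Exception as exc:
        raise type(exc)(f"[stage: read counts] {exc}") from exc
    try:
        expr = normalize(cm, size_factors(cm))
    except Exception as exc:
        raise type(exc)(f"[stage: normalize] {exc}") from exc

    window = CisWindow(anchor_chrom, anchor_pos, window_bp)
    plan = PermutationPlan(B=permutations, seed=seed,
                           enumeration_cap=enumeration_cap, side=side)
    result = run_scan(
        g, expr, gene, window, plan,
        sample_subset=sample_subset, min_group_n=min_group_n,
        log_expression=log_expression,
    )

    planted_ids: set[str] = set()
    if truth is not None:
        tdf = pd.read_csv(truth, sep="\t", dtype={"variant": str})
        planted_ids = set(tdf.loc[tdf["kind"] == "eqtl", "variant"])

    paths: dict[str, str] = {}
    for method, records in (("linear", result.linear),
                            ("directional", result.directional)):
        if records:
            q = bh_adjust([r.p for r in records])
            for rec, adj in zip(records, q):
                rec.p_adjusted = float(adj)
        table_path = outdir / f"{method}.tsv"
        write_eqtl_table(records, table_path)
        if planted_ids:
            df = pd.read_csv(table_path, sep="\t")
            df["planted"] = df["snp"].isin(planted_ids)
            df.to_csv(table_path, sep="\t", index=False)
        paths[method] = str(table_path)
        if records:
            scan = alpha_scan([r.p for r in records], step=alpha_step)
            ap = outdir / f"alpha_scan_{method}.tsv"
            write_alpha_scan(scan, ap)
            paths[f"alpha_scan_{method}"] = str(ap)

    _write_manifest(outdir / "manifest.json", "eqtl", {
        "inputs": {"genotypes": str(genotypes), "counts": str(counts),
                   "truth": str(truth) if truth else None},
        "gene": gene,
        "window": {"chrom": anchor_chrom, "pos": anchor_pos, "bp": window_bp},
        "plan": {"B": permutations, "seed": seed, "side": side,
                 "enumeration_cap": enumeration_cap},
        "alpha_step": alpha_step,
        "min_group_n": min_group_n,
        "log_expression": log_expression,
        "sample_subset": sample_subset,
        "n_tested": {"linear": len(result.linear),
                     "directional": len(result.directional)},
        "n_skipped": result.n_skipped,
        "skipped": result.skipped,
        "outputs": paths,
        "seed": seed,
    })
    logger.info("eqtl: %d linear / %d directional records, %d skipped",
                len(result.linear), len(result.directional), result.n_skipped)
    return paths


def run_compare_groups(
    counts: str | Path,
    samples: str | Path,
    gene: str,
    out: str | Path | None = None,
    test: str = "wilcoxon",
) -> dict:
    """Case/control comparison of one gene's normalized expression; returns
    the comparison as a dict and optionally writes it as a one-row TSV."""
    cm = read_counts(counts)
    sheet = read_sample_sheet(samples)
    expr = normalize(cm, size_factors(cm))
    comp = compare_groups(expr.gene(gene), expr.samples, sheet, test=test)
    row = dataclasses.asdict(comp)
    if out is not None:
        pd.DataFrame([row]).to_csv(out, sep="\t", index=False)
    return row


def run_coexpr(
    counts: str | Path,
    target_gene: str,
    outdir: str | Path,
    r_min: float = 0.30,
    p_max: float = 0.05,
    strict_r: float | None = None,
) -> str:
    """Co-expression screen against the target gene; writes the Table-3-style
    TSV plus a manifest and returns the table path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm = read_counts(counts)
    expr = normalize(cm, size_factors(cm))
    records = coexpression_screen(
        expr, target_gene, r_min=r_min, p_max=p_max, strict_r=strict_r
    )
    path = outdir / "coexpression.tsv"
    write_coexpr_table(records, path)
    _write_manifest(outdir / "manifest.json", "coexpr", {
        "inputs": {"counts": str(counts)},
        "target_gene": target_gene,
        "thresholds": {"r_min": r_min, "p_max": p_max, "strict_r": strict_r},
        "n_genes": len(records),
        "outputs": {"coexpression": str(path)},
    })
    return str(path)
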