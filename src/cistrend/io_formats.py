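"""Readers and writers for every external representation the pipeline touches.

Genotypes come in as VCF (parsed with cyvcf2) or as a hand-writable dosage TSV
(header ``sample <variant_id>...``, cells in {0,1,2,NA}); counts and sample
sheets are plain TSVs; results go out as UTF-8 tab-delimited tables with dot
decimals. All coordinates are 1-based inclusive, exactly as in VCF POS.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._types import (
    CoexprRecord,
    CountMatrix,
    EqtlRecord,
    GenotypeMatrix,
    SampleSheet,
    VariantMeta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_eqtl_table",
    "read_eqtl_table",
    "write_alpha_scan",
    "write_coexpr_table",
]

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")

_EQTL_COLUMNS = [
    "snp",
    "gene_context",
    "position",
    "allele1",
    "allele2",
    "method",
    "statistic",
    "direction",
    "p",
    "p_adjusted",
]


def _parse_region(region: str) -> tuple[str, int, int]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"region must look like 'chrom:start-end', got {region!r}")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def read_vcf(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into an alt-dosage GenotypeMatrix.

    GT "0/0" -> 0, "0/1"/"1/0" -> 1, "1/1" -> 2, "./." -> NaN; phase
    separators are ignored. Multi-allelic and non-SNV records are skipped
    (count logged). ``region`` is ``chrom:start-end``, 1-based inclusive,
    applied while streaming so no index is required.

    Raises OSError for an unreadable file and ValueError when no variant
    survives filtering.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"VCF not found: {path}")
    want: tuple[str, int, int] | None = _parse_region(region) if region else None

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantMeta] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        if want is not None:
            chrom, start, end = want
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown/missing
        gt = np.asarray(rec.gt_types, dtype=float)
        dos = np.full_like(gt, np.nan)
        dos[gt == 0] = 0.0
        dos[gt == 1] = 1.0
        dos[gt == 3] = 2.0
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(VariantMeta(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        rows.append(dos)
    vcf.close()

    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNV records", n_skipped)
    if not variants:
        raise ValueError(
            f"no biallelic SNVs in {path}"
            + (f" within region {region}" if region else "")
        )
    dosage = np.column_stack(rows)
    return GenotypeMatrix(samples, variants, dosage)


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 file (via pysam)."""
    import pysam

    path = Path(path)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(v.chrom for v in g.variants):
        header.contigs.add(chrom)
    for s in g.samples:
        header.add_sample(s)
    gt_of = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(range(g.n_variants),
                       key=lambda j: (g.variants[j].chrom, g.variants[j].pos))
        for j in order:
            v = g.variants[j]
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt), id=v.id,
            )
            for i, s in enumerate(g.samples):
                d = g.dosage[i, j]
                rec.samples[s]["GT"] = (None, None) if math.isnan(d) else gt_of[d]
            out.write(rec)


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage TSV dialect: one ``#variant`` metadata line per
    variant (id, chrom, pos, ref, alt), then ``sample <id>...`` with cells in
    {0,1,2,NA}."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for v in g.variants:
            fh.write(f"#variant\t{v.id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")
        fh.write("sample\t" + "\t".join(g.variant_ids()) + "\n")
        for i, s in enumerate(g.samples):
            cells = [
                "NA" if math.isnan(d) else str(int(d)) for d in g.dosage[i, :]
            ]
            fh.write(s + "\t" + "\t".join(cells) + "\n")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the dosage TSV dialect written by :func:`write_dosage_tsv`."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"dosage TSV not found: {path}")
    meta: dict[str, VariantMeta] = {}
    header: list[str] | None = None
    samples: list[str] = []
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#variant":
                if len(fields) != 6:
                    raise ValueError(f"line {lineno}: malformed #variant line")
                _, vid, chrom, pos, ref, alt = fields
                meta[vid] = VariantMeta(vid, chrom, int(pos), ref, alt)
            elif header is None:
                if fields[0] != "sample":
                    raise ValueError(f"line {lineno}: expected 'sample' header")
                header = fields[1:]
            else:
                if len(fields) != len(header) + 1:
                    raise ValueError(f"line {lineno}: wrong number of cells")
                samples.append(fields[0])
                row = []
                for vid, cell in zip(header, fields[1:]):
                    if cell == "NA":
                        row.append(float("nan"))
                    elif cell in ("0", "1", "2"):
                        row.append(float(cell))
                    else:
                        raise ValueError(
                            f"line {lineno}, variant {vid}: cell {cell!r} "
                            "not in {0,1,2,NA}"
                        )
                rows.append(row)
    if header is None or not rows:
        raise ValueError(f"empty dosage TSV: {path}")
    variants = []
    for vid in header:
        if vid not in meta:
            raise ValueError(f"variant {vid} has no #variant metadata line")
        variants.append(meta[vid])
    return GenotypeMatrix(samples, variants, np.array(rows))


def read_counts(path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene id, header row of
    sample ids). Non-integer, negative or missing cells are fatal, with the
    offending row/column named."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"count TSV not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty count file: {path}") from None
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty count file: {path}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(f"missing cell at gene {gene!r}, sample {col!r}")
    arr = df.to_numpy()
    frac = arr != np.floor(arr)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count {arr[i, j]} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return CountMatrix(
        [str(x) for x in df.index], [str(x) for x in df.columns],
        arr.astype(np.int64),
    )


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a two-column TSV ``sample<TAB>status`` with a header row."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"sample sheet not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    if df["status"].isna().any() or df["sample"].isna().any():
        raise ValueError("sample sheet has missing cells")
    return SampleSheet(df["sample"].tolist(), df["status"].tolist())


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame({"sample": sheet.samples, "status": sheet.status}).to_csv(
        path, sep="\t", index=False
    )


def write_eqtl_table(records: Sequence[EqtlRecord], path: str | Path) -> None:
    """Write per-variant test outcomes as a TSV (header always present;
    an empty record list yields a header-only file)."""
    rows = [
        {
            "snp": r.variant.id,
            "gene_context": "NA",
            "position": r.variant.pos,
            "allele1": r.variant.ref,
            "allele2": r.variant.alt,
            "method": r.method,
            "statistic": repr(r.statistic),
            "direction": r.direction,
            "p": repr(r.p),
            "p_adjusted": repr(r.p_adjusted),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_EQTL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_eqtl_table(path: str | Path, chrom: str = "NA") -> list[EqtlRecord]:
    """Re-read a table written by :func:`write_eqtl_table`.

    The TSV does not carry the chromosome (Table-2 layout); pass ``chrom`` to
    restore it. Round-trips every written field losslessly (statistics and
    p-values are serialized with ``repr``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str},
                     float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        out.append(
            EqtlRecord(
                variant=VariantMeta(
                    str(row["snp"]), chrom, int(row["position"]),
                    str(row["allele1"]), str(row["allele2"]),
                ),
                method=row["method"],
                statistic=float(row["statistic"]),
                direction=row["direction"],
                p=float(row["p"]),
                p_adjusted=float(row["p_adjusted"]),
            )
        )
    return out


def write_alpha_scan(result, path: str | Path) -> None:
    """Write an AlphaScanResult as TSV (columns alpha, observed, expected,
    ratio) with a trailing ``#alpha_star`` summary line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("alpha\tobserved\texpected\tratio\n")
        for a, o, e, r in zip(
            result.grid, result.observed, result.expected, result.ratio
        ):
            fh.write(f"{a:.6g}\t{o}\t{e!r}\t{r!r}\n")
        star = "NA" if result.alpha_star is None else f"{result.alpha_star:.6g}"
        fh.write(f"#alpha_star\t{star}\n")


def write_coexpr_table(records: Iterable[CoexprRecord], path: str | Path) -> None:
    """Write co-expression screen results, one row per gene."""
    rows = [
        {
            "gene": r.gene,
            "correlation": repr(r.r),
            "p": repr(r.p),
            "n": r.n,
            "p_bonferroni": repr(r.p_bonferroni),
            "p_bh": repr(r.p_bh),
            "class": r.klass,
            "constant": r.constant,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["gene", "correlation", "p", "n", "p_bonferroni", "p_bh",
                 "class", "constant"],
    ).to_csv(path, sep="\t", index=False)
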