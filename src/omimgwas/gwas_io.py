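"""Readers and writers for the pipeline's file dialects.

Summary statistics are tab-delimited with a header (SNP, CHR, POS, P,
MAF; case-insensitive, extra columns ignored, gzip transparent via
pandas).  Gene loci come as a header-ed TSV (symbol, chrom, start, end,
strand; 1-based closed) or as BED (0-based half-open, converted on
read).  Reference panels are plain sample-by-SNP dosage TSVs or VCFs
(dosage = count of non-reference GT alleles, read through pysam).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .window_mapping import VARIANT_COLUMNS, GeneLocus

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_gene_loci",
    "write_gene_loci",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_panel_vcf",
    "write_panel_vcf",
]

_COLUMN_ALIASES = {
    "snp": "snp",
    "rsid": "snp",
    "variant_id": "snp",
    "chr": "chr",
    "chrom": "chr",
    "chromosome": "chr",
    "pos": "pos",
    "bp": "pos",
    "position": "pos",
    "p": "p",
    "pval": "p",
    "pvalue": "p",
    "p_value": "p",
    "maf": "maf",
    "freq": "maf",
}


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistic table into canonical columns."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    renames = {}
    for col in df.columns:
        canon = _COLUMN_ALIASES.get(str(col).strip().lower())
        if canon and canon not in renames.values():
            renames[col] = canon
    df = df.rename(columns=renames)
    missing = [c for c in ("snp", "chr", "pos", "p") if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistic file lacks columns: {missing}")
    if "maf" not in df.columns:
        df["maf"] = np.nan
    df = df[list(VARIANT_COLUMNS)].copy()
    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64)
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    df["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    bad = df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows with p-values outside (0, 1]")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    out = df[list(VARIANT_COLUMNS)].rename(
        columns={"snp": "SNP", "chr": "CHR", "pos": "POS", "p": "P", "maf": "MAF"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_gene_loci(path: str | Path) -> list[GeneLocus]:
    """Read gene loci from TSV (1-based closed) or BED (converted)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
            dtype={"chrom": str, "name": str, "strand": str},
        )
        return [
            GeneLocus(
                gene_symbol=str(name),
                chromosome=str(chrom),
                tx_start=int(start) + 1,  # BED is 0-based half-open
                tx_end=int(end),
                strand=str(strand) if pd.notna(strand) else "?",
            )
            for chrom, start, end, name, strand in zip(
                bed["chrom"], bed["start"], bed["end"], bed["name"], bed["strand"]
            )
        ]
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
    required = {"symbol", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"loci file must have columns {sorted(required)}")
    return [
        GeneLocus(
            gene_symbol=str(row.symbol),
            chromosome=str(row.chrom),
            tx_start=int(row.start),
            tx_end=int(row.end),
            strand=str(getattr(row, "strand", "?")) if "strand" in df.columns else "?",
        )
        for row in df.itertuples(index=False)
    ]


def write_gene_loci(loci: Sequence[GeneLocus], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "symbol": l.gene_symbol,
                "chrom": l.chromosome,
                "start": l.tx_start,
                "end": l.tx_end,
                "strand": l.strand,
            }
            for l in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    """Sample-by-SNP dosage matrix; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_panel_tsv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index_label="sample")


def read_panel_vcf(path: str | Path) -> pd.DataFrame:
    """Read GT dosages (count of non-reference alleles) from a VCF."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        ids: list[str] = []
        columns: list[np.ndarray] = []
        for record in vcf:
            vid = record.id or f"{record.chrom}:{record.pos}"
            dosage = np.zeros(len(samples), dtype=np.int8)
            for i, sample in enumerate(samples):
                gt = record.samples[sample].get("GT") or ()
                dosage[i] = sum(1 for a in gt if a not in (None, 0))
            ids.append(vid)
            columns.append(dosage)
    return pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0), dtype=np.int8),
        index=samples,
        columns=ids,
    )


def write_panel_vcf(
    panel: pd.DataFrame,
    path: str | Path,
    chromosomes: Sequence[str] | None = None,
    positions: Sequence[int] | None = None,
) -> None:
    """Write a minimal diploid GT VCF for a 0/1/2 dosage matrix."""
    snps = [str(c) for c in panel.columns]
    n = len(snps)
    chroms = [str(c) for c in (chromosomes if chromosomes is not None else ["1"] * n)]
    poss = [int(p) for p in (positions if positions is not None else range(1, n + 1))]
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for contig in dict.fromkeys(chroms):
            handle.write(f"##contig=<ID={contig}>\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.index)
            + "\n"
        )
        values = panel.to_numpy()
        for j, snp in enumerate(snps):
            gts = "\t".join(gt_of[int(v)] for v in values[:, j])
            handle.write(f"{chroms[j]}\t{poss[j]}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
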