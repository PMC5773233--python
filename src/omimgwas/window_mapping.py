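"""Candidate-gene windows and variant capture for GWAS summary statistics.

Given a list of candidate gene loci, build flanking windows (by default
±50 kb around the transcription span, the scale at which most regulatory
GWAS signals sit relative to their target gene) and select the
summary-statistic variants falling inside them.  Coordinates are 1-based
closed intervals throughout; BED input is converted on read (see
:mod:`omimgwas.io`).

The selection keeps two views: a deduplicated global list (a variant
near two candidate genes counts once in genome-wide exceedance counts)
and per-gene lists that retain shared variants (as required by the
gene-based test, where each gene is scored on everything in its own
window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUTOSOMES",
    "GeneLocus",
    "GenomicInterval",
    "VariantAssoc",
    "WindowSelection",
    "normalize_chromosome",
    "chromosome_sort_key",
    "variants_frame",
    "make_windows",
    "select_variants",
    "filter_autosomal",
    "filter_maf",
]

#: Canonical autosome labels after normalization.
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

_SPECIAL = {"23": "X", "24": "Y", "25": "MT", "M": "MT"}

#: Canonical column order for summary-statistic tables.
VARIANT_COLUMNS = ("snp", "chr", "pos", "p", "maf")


@dataclass(frozen=True)
class GeneLocus:
    """A gene's transcription span on a chromosome (1-based, inclusive)."""

    gene_symbol: str
    chromosome: str
    tx_start: int
    tx_end: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_symbol}: tx_start > tx_end")
        if not self.chromosome:
            raise ValueError(f"{self.gene_symbol}: empty chromosome")


@dataclass(frozen=True)
class GenomicInterval:
    """A variant-capture window derived from a gene locus."""

    chromosome: str
    start: int
    end: int
    gene_symbol: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval {self.chromosome}:{self.start}-{self.end}")


@dataclass(frozen=True)
class VariantAssoc:
    """One GWAS summary record."""

    variant_id: str
    chromosome: str
    position: int
    p_value: float
    maf: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.variant_id}: p-value must be in (0, 1]")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")


def normalize_chromosome(label: str, strict: bool = False) -> str | None:
    """Harmonize a chromosome label: strip ``chr``, uppercase, 23 -> X.

    Returns the canonical label, or ``None`` for unrecognized labels in
    lenient mode (``strict=False``); strict mode raises instead.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    s = _SPECIAL.get(s, s)
    if s in AUTOSOMES or s in ("X", "Y", "MT"):
        return s
    if strict:
        raise ValueError(f"unrecognized chromosome label {label!r}")
    return None


def chromosome_sort_key(label: str) -> tuple[int, int | str]:
    """Deterministic genome ordering: 1..22, X, Y, MT, then others."""
    order = {"X": 23, "Y": 24, "MT": 25}
    if label in AUTOSOMES:
        return (0, int(label))
    if label in order:
        return (0, order[label])
    return (1, label)


def variants_frame(records: Iterable[VariantAssoc]) -> pd.DataFrame:
    """Build the canonical summary-statistic table from variant records."""
    rows = [
        (v.variant_id, v.chromosome, v.position, v.p_value, np.nan if v.maf is None else v.maf)
        for v in records
    ]
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))


def make_windows(loci: Sequence[GeneLocus], flank_bp: int) -> list[GenomicInterval]:
    """One capture window per locus: ``[max(1, start - flank), end + flank]``.

    Strand is ignored; the flank is symmetric.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    return [
        GenomicInterval(
            chromosome=locus.chromosome,
            start=max(1, locus.tx_start - flank_bp),
            end=locus.tx_end + flank_bp,
            gene_symbol=locus.gene_symbol,
        )
        for locus in loci
    ]


@dataclass
class WindowSelection:
    """Variants captured by candidate-gene windows.

    ``variants`` is the full input table (index reset); ``per_gene`` maps
    each gene symbol to the row indices of its window's variants;
    ``global_index`` holds the deduplicated union in canonical
    (chromosome, position, id) order.
    """

    variants: pd.DataFrame
    per_gene: dict[str, np.ndarray]
    global_index: np.ndarray
    flank_bp: int | None = None
    n_genes: int = 0

    @property
    def global_variants(self) -> pd.DataFrame:
        return self.variants.iloc[self.global_index]

    @property
    def n_selected(self) -> int:
        return int(len(self.global_index))

    def gene_variants(self, gene_symbol: str) -> pd.DataFrame:
        return self.variants.iloc[self.per_gene[gene_symbol]]


def _canonical_order(df: pd.DataFrame, idx: np.ndarray) -> np.ndarray:
    chroms = df["chr"].iloc[idx].map(lambda c: chromosome_sort_key(str(c)))
    sub = pd.DataFrame(
        {
            "ck": chroms.to_numpy(),
            "pos": df["pos"].iloc[idx].to_numpy(),
            "snp": df["snp"].iloc[idx].to_numpy(),
        }
    )
    order = sub.sort_values(["ck", "pos", "snp"], kind="stable").index.to_numpy()
    return idx[order]


def select_variants(
    variants: pd.DataFrame, windows: Sequence[GenomicInterval]
) -> WindowSelection:
    """Select variants inside capture windows (inclusive boundaries).

    A variant belongs to gene *g* iff it sits on the same (normalized)
    chromosome with ``start <= pos <= end``.  The global union counts
    each distinct variant once even when several overlapping windows
    capture it; ordering is deterministic by (chromosome, position, id).
    """
    df = variants.reset_index(drop=True)
    n = len(df)
    per_gene: dict[str, np.ndarray] = {}
    in_any = np.zeros(n, dtype=bool)

    by_chr: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if n:
        norm = df["chr"].map(lambda c: normalize_chromosome(c) or str(c))
        for label, sub in df.groupby(norm.to_numpy()):
            pos = sub["pos"].to_numpy(dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            by_chr[str(label)] = (sub.index.to_numpy()[order], pos[order])

    empty = np.array([], dtype=np.int64)
    for w in windows:
        label = normalize_chromosome(w.chromosome) or str(w.chromosome)
        idx, pos = by_chr.get(label, (empty, empty))
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        hit = idx[lo:hi]
        hit = _canonical_order(df, np.asarray(hit, dtype=np.int64)) if len(hit) else hit
        per_gene[w.gene_symbol] = np.asarray(hit, dtype=np.int64)
        in_any[hit] = True

    union = np.flatnonzero(in_any)
    if len(union):
        # Drop duplicate physical variants (same id at same site) so the
        # global list counts each variant once.
        key = pd.DataFrame(
            {
                "chr": df["chr"].iloc[union].to_numpy(),
                "pos": df["pos"].iloc[union].to_numpy(),
                "snp": df["snp"].iloc[union].to_numpy(),
            }
        )
        union = union[~key.duplicated().to_numpy()]
        union = _canonical_order(df, union)
    return WindowSelection(
        variants=df,
        per_gene=per_gene,
        global_index=np.asarray(union, dtype=np.int64),
        flank_bp=None,
        n_genes=len({w.gene_symbol for w in windows}),
    )


def filter_autosomal(
    loci: Sequence[GeneLocus], on_unrecognized: str = "exclude"
) -> tuple[list[GeneLocus], list[GeneLocus]]:
    """Partition loci into autosomal and excluded (X/Y/MT or unknown).

    ``on_unrecognized`` is ``"exclude"`` (lenient, default) or
    ``"error"`` (strict).
    """
    if on_unrecognized not in ("exclude", "error"):
        raise ValueError("on_unrecognized must be 'exclude' or 'error'")
    kept: list[GeneLocus] = []
    excluded: list[GeneLocus] = []
    for locus in loci:
        label = normalize_chromosome(locus.chromosome, strict=(on_unrecognized == "error"))
        if label in AUTOSOMES:
            kept.append(locus)
        else:
            excluded.append(locus)
    return kept, excluded


def filter_maf(variants: pd.DataFrame, min_maf: float) -> tuple[pd.DataFrame, int]:
    """Keep variants with MAF strictly above ``min_maf``.

    Variants with missing MAF are retained (their count is returned as a
    warning tally), mirroring meta-analysis files where frequency is not
    always reported.
    """
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = pd.to_numeric(variants["maf"], errors="coerce")
    missing = maf.isna()
    keep = missing | (maf > min_maf)
    return variants.loc[keep].reset_index(drop=True), int(missing.sum())
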