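"""Synthetic inputs with planted ground truth for the whole pipeline.

Every input the analysis consumes can be generated here as a pure
function of a configuration and a seed: candidate gene loci, an
LD-structured reference genotype panel, GWAS summary statistics under
null or enriched regimes, OMIM-style phenotype record fixtures with
their mapping tables, and a GMT annotation catalog with one deliberately
enriched term.  Each generator returns (or contributes to) a
:class:`GroundTruthManifest` recording what was planted, so recovery can
be checked exactly.

Model sketch
------------
Variants sit on a grid of uniformly placed positions partitioned into
consecutive LD blocks.  Within a block, a latent Gaussian field with
AR(1) correlation rho^|i-j| drives both the panel genotypes (two latent
haplotypes per individual, thresholded at each SNP's allele frequency,
summed to 0/1/2 dosages) and the summary-statistic z-scores (one MVN
draw per block).  Under the enriched regime, a causal SNP is picked
inside each causal gene's window and its non-centrality lambda
propagates to block-mates as lambda * r (the usual LD-propagation of an
association signal), after which p = 2 * Phi(-|z|).  Drawing z directly
from the LD-implied MVN gives the same sampling distribution as
simulating phenotypes and regressing, at a small fraction of the cost.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .overrep import AnnotationCatalog
from .phenotype_mining import CLASS_LABELS, TermLexicon
from .window_mapping import GeneLocus

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "VariantGrid",
    "ReferencePanel",
    "gen_gene_loci",
    "gen_variant_grid",
    "gen_reference_panel",
    "gen_summary_stats",
    "gen_omim_fixture",
    "gen_annotation_catalog",
    "generate_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study, with desk-scale defaults.

    The defaults emulate a candidate-gene scan at a scale that runs in
    seconds: a 2 x 100 Mb genome carrying 100 genes and 20,000 common
    variants in AR(1) LD blocks (so the ±50 kb candidate windows cover
    under a tenth of the genome — sparse, as in a real genome-wide scan),
    a 2,000-sample reference panel, ten causal genes with a lambda = 6
    association spike (|z| ~ 6 at the causal SNP, i.e. p ~ 2e-9), and a
    100-term annotation catalog over a 1,000-gene universe with one
    ten-fold-enriched term.
    """

    n_chromosomes: int = 2
    chromosome_length_bp: int = 100_000_000
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (5_000, 100_000)
    flank_bp: int = 50_000
    n_variants: int = 20_000
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.7
    n_reference_samples: int = 2_000
    causal_gene_fraction: float = 0.10
    effect_lambda: float = 6.0
    n_omim_records: int = 30
    class_mix: tuple[tuple[str, float], ...] = (
        ("myopia", 0.60),
        ("hyperopia", 0.20),
        ("astigmatism", 0.10),
        ("ametropia_other", 0.10),
    )
    multi_class_prob: float = 0.15
    unlinked_fraction: float = 0.25
    shared_gene_prob: float = 0.08
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 60)
    enriched_term_size: int = 60
    enriched_fold: float = 10.0
    n_universe: int = 1_000

    def __post_init__(self) -> None:
        if min(
            self.n_chromosomes,
            self.chromosome_length_bp,
            self.n_genes,
            self.n_variants,
            self.n_reference_samples,
            self.n_terms,
            self.n_universe,
        ) <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.effect_lambda < 0:
            raise ValueError("effect_lambda must be >= 0")
        weights = [w for _, w in self.class_mix]
        if any(w < 0 for w in weights) or not np.isclose(sum(weights), 1.0):
            raise ValueError("class_mix weights must be non-negative and sum to 1")


@dataclass
class GroundTruthManifest:
    """Everything a generator planted, plus the parameters that made it."""

    seed: int
    params: dict
    causal_genes: tuple[str, ...] = ()
    causal_snp_by_gene: dict[str, str] = field(default_factory=dict)
    planted_classes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    gene_by_mim: dict[str, str | None] = field(default_factory=dict)
    unlinked_mim_ids: tuple[str, ...] = ()
    enriched_term_id: str | None = None
    enriched_term_n_causal: int = 0

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(data, handle, indent=2, default=list)

    def expected_gene_sets(self) -> dict[str, set[str]]:
        """Per-class gene sets implied by the planted record fixture."""
        out: dict[str, set[str]] = {f"any-{c}": set() for c in ("myopia", "hyperopia", "astigmatism")}
        out["all-ametropia"] = set()
        for label in CLASS_LABELS:
            out[f"{label}-only"] = set()
        for mim, classes in self.planted_classes.items():
            gene = self.gene_by_mim.get(mim)
            if gene is None:
                continue
            for c in classes:
                if f"any-{c}" in out:
                    out[f"any-{c}"].add(gene)
            out["all-ametropia"].add(gene)
            if len(classes) == 1:
                out[f"{classes[0]}-only"].add(gene)
        return out


def _config_dict(config: SyntheticConfig) -> dict:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# gene loci


def gen_gene_loci(config: SyntheticConfig, seed: int) -> list[GeneLocus]:
    """Place non-overlapping transcription spans uniformly per chromosome."""
    rng = np.random.default_rng([int(seed), 11])
    counts = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        counts[i] += 1
    lo, hi = config.gene_length_range
    loci: list[GeneLocus] = []
    gene_no = 0
    for chrom_i, count in enumerate(counts, start=1):
        if count == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=count)
        slack = config.chromosome_length_bp - int(lengths.sum())
        if slack < count:
            raise ValueError(
                f"chromosome {chrom_i} too short for {count} genes of {lo}-{hi} bp"
            )
        gaps = np.sort(rng.integers(0, slack + 1, size=count))
        starts = 1 + gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))
        for j in range(count):
            gene_no += 1
            loci.append(
                GeneLocus(
                    gene_symbol=f"GENE{gene_no:04d}",
                    chromosome=str(chrom_i),
                    tx_start=int(starts[j]),
                    tx_end=int(starts[j] + lengths[j] - 1),
                    strand=str(rng.choice(["+", "-"])),
                )
            )
    return loci


# ---------------------------------------------------------------------------
# variant grid, reference panel


@dataclass
class VariantGrid:
    """The variant scaffold shared by the panel and the summary statistics."""

    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    maf: np.ndarray
    block_ids: np.ndarray

    @property
    def n(self) -> int:
        return int(self.snp_ids.size)

    def block_slices(self) -> list[slice]:
        """Consecutive index ranges, one per LD block."""
        ids = self.block_ids
        boundaries = np.flatnonzero(np.diff(ids)) + 1
        edges = np.concatenate(([0], boundaries, [ids.size]))
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def gen_variant_grid(config: SyntheticConfig, seed: int) -> VariantGrid:
    """Uniform variant positions, drawn MAFs, and LD-block assignment."""
    rng = np.random.default_rng([int(seed), 12])
    counts = [config.n_variants // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_variants % config.n_chromosomes):
        counts[i] += 1
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    block_base = 0
    for chrom_i, count in enumerate(counts, start=1):
        pos = np.unique(rng.integers(1, config.chromosome_length_bp + 1, size=count))
        while pos.size < count:
            extra = rng.integers(1, config.chromosome_length_bp + 1, size=count - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(pos[:count])
        chroms.append(np.full(count, str(chrom_i), dtype=object))
        positions.append(pos)
        blocks.append(block_base + np.arange(count) // config.ld_block_size)
        block_base = int(blocks[-1][-1]) + 1 if count else block_base
    n = config.n_variants
    return VariantGrid(
        snp_ids=np.array([f"rs{i + 1:07d}" for i in range(n)], dtype=object),
        chromosomes=np.concatenate(chroms),
        positions=np.concatenate(positions).astype(np.int64),
        maf=rng.uniform(config.maf_range[0], config.maf_range[1], size=n),
        block_ids=np.concatenate(blocks).astype(np.int64),
    )


def _ar1_block(rng: np.random.Generator, n_rows: int, k: int, rho: float) -> np.ndarray:
    """Rows of a standard AR(1) Gaussian vector: corr(z_i, z_j) = rho^|i-j|."""
    e = rng.standard_normal((n_rows, k))
    if rho == 0.0 or k == 1:
        return e
    z = np.empty_like(e)
    z[:, 0] = e[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, k):
        z[:, j] = rho * z[:, j - 1] + c * e[:, j]
    return z


@dataclass
class ReferencePanel:
    """Diploid dosage panel over the variant grid (samples x SNPs, 0/1/2)."""

    grid: VariantGrid
    dosages: np.ndarray  # int8, shape (n_samples, n_variants)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.grid.snp_ids

    @property
    def n_samples(self) -> int:
        return int(self.dosages.shape[0])

    def dosages_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        index = {str(s): i for i, s in enumerate(self.grid.snp_ids)}
        cols = [index[str(s)] for s in snp_ids]
        return self.dosages[:, cols].astype(float)

    def empirical_maf(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages,
            columns=[str(s) for s in self.grid.snp_ids],
            index=[f"S{i + 1:05d}" for i in range(self.n_samples)],
        )


def gen_reference_panel(config: SyntheticConfig, seed: int) -> ReferencePanel:
    """Simulate the LD reference panel over the (seed-matched) variant grid.

    Two latent AR(1) haplotype fields per individual are thresholded at
    each SNP's allele frequency and summed, so dosages are 0/1/2 with
    approximately the drawn MAF and block-local LD.
    """
    grid = gen_variant_grid(config, seed)
    rng = np.random.default_rng([int(seed), 13])
    n = config.n_reference_samples
    dosages = np.empty((n, grid.n), dtype=np.int8)
    thresholds = stats.norm.isf(grid.maf)
    for block in grid.block_slices():
        k = block.stop - block.start
        latent = _ar1_block(rng, 2 * n, k, config.ld_rho)
        alleles = latent > thresholds[np.newaxis, block]
        dosages[:, block] = (
            alleles[:n].astype(np.int8) + alleles[n:].astype(np.int8)
        )
    return ReferencePanel(grid=grid, dosages=dosages)


# ---------------------------------------------------------------------------
# summary statistics


def gen_summary_stats(
    config: SyntheticConfig,
    loci: Sequence[GeneLocus],
    panel: ReferencePanel | VariantGrid | None,
    seed: int,
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Draw per-variant z-scores block-wise and convert to p-values.

    ``panel`` supplies the variant grid (a :class:`ReferencePanel`, a
    bare :class:`VariantGrid`, or ``None`` to regenerate the grid from
    the same seed).  Under the enriched regime a causal SNP is chosen
    near the midpoint of each causal gene's window and its
    non-centrality propagates through the block as lambda * rho^|i-j|.
    """
    if isinstance(panel, ReferencePanel):
        grid = panel.grid
    elif isinstance(panel, VariantGrid):
        grid = panel
    else:
        grid = gen_variant_grid(config, seed)
    rng_pick = np.random.default_rng([int(seed), 14])
    rng_noise = np.random.default_rng([int(seed), 15])

    symbols = sorted(l.gene_symbol for l in loci)
    n_causal = int(round(config.causal_gene_fraction * len(loci)))
    causal_symbols = (
        sorted(rng_pick.choice(symbols, size=n_causal, replace=False).tolist())
        if n_causal and config.effect_lambda > 0
        else []
    )
    by_symbol = {l.gene_symbol: l for l in loci}

    mu = np.zeros(grid.n)
    causal_snp_by_gene: dict[str, str] = {}
    block_of = grid.block_ids
    for symbol in causal_symbols:
        locus = by_symbol[symbol]
        lo = max(1, locus.tx_start - config.flank_bp)
        hi = locus.tx_end + config.flank_bp
        on_chrom = np.flatnonzero(grid.chromosomes == locus.chromosome)
        if on_chrom.size == 0:
            on_chrom = np.arange(grid.n)
        in_window = on_chrom[
            (grid.positions[on_chrom] >= lo) & (grid.positions[on_chrom] <= hi)
        ]
        candidates = in_window if in_window.size else on_chrom
        midpoint = (locus.tx_start + locus.tx_end) // 2
        c = int(candidates[np.argmin(np.abs(grid.positions[candidates] - midpoint))])
        causal_snp_by_gene[symbol] = str(grid.snp_ids[c])
        mates = np.flatnonzero(block_of == block_of[c])
        mu[mates] += config.effect_lambda * config.ld_rho ** np.abs(mates - c)

    z = mu.copy()
    for block in grid.block_slices():
        k = block.stop - block.start
        z[block] += _ar1_block(rng_noise, 1, k, config.ld_rho)[0]
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    variants = pd.DataFrame(
        {
            "snp": grid.snp_ids,
            "chr": grid.chromosomes,
            "pos": grid.positions,
            "p": p,
            "maf": grid.maf,
        }
    )
    manifest = GroundTruthManifest(
        seed=int(seed),
        params=_config_dict(config),
        causal_genes=tuple(causal_symbols),
        causal_snp_by_gene=causal_snp_by_gene,
    )
    return variants, manifest


# ---------------------------------------------------------------------------
# OMIM-style fixture


_FILLER_FEATURES = (
    "Cataract",
    "Short stature",
    "Sensorineural deafness",
    "Joint hypermobility",
    "Cleft palate",
    "Scoliosis",
    "Developmental delay",
    "Retinal dystrophy",
    "Ectopia lentis",
    "Blue sclerae",
    "Glaucoma",
    "Micrognathia",
    "Arachnodactyly",
)


def gen_omim_fixture(
    config: SyntheticConfig,
    seed: int,
    gene_symbols: Sequence[str] | None = None,
    lexicon: TermLexicon | None = None,
) -> tuple[str, str, str, GroundTruthManifest]:
    """Generate record text plus morbidmap/gene-id tables with planted truth.

    Each record receives one refractive class from the configured mix
    (sometimes two), realized as lexicon terms embedded in an otherwise
    term-free clinical synopsis; a configurable fraction of records get
    no gene link, and a small fraction reuse an already-linked gene so
    deduplication has something to collapse.
    """
    rng = np.random.default_rng([int(seed), 16])
    lexicon = lexicon or TermLexicon.default()
    labels = [label for label, _ in config.class_mix]
    weights = np.array([w for _, w in config.class_mix], dtype=float)
    weights = weights / weights.sum()

    pool = [str(s) for s in gene_symbols] if gene_symbols else [
        f"GENE{i + 1:04d}" for i in range(max(config.n_omim_records, 1))
    ]
    mims: list[str] = []
    seen_mims: set[str] = set()
    while len(mims) < config.n_omim_records:
        candidate = f"{int(rng.integers(100000, 700000)):06d}"
        if candidate not in seen_mims:
            seen_mims.add(candidate)
            mims.append(candidate)

    record_chunks: list[str] = []
    morbid_rows: list[str] = []
    planted: dict[str, tuple[str, ...]] = {}
    gene_by_mim: dict[str, str | None] = {}
    used_genes: list[str] = []
    fresh_i = 0
    for i, mim in enumerate(mims):
        classes = [str(rng.choice(labels, p=weights))]
        if rng.random() < config.multi_class_prob:
            other = [l for l in labels if l != classes[0]]
            classes.append(str(rng.choice(other)))
        planted[mim] = tuple(sorted(classes))

        features = list(
            rng.choice(_FILLER_FEATURES, size=3, replace=False)
        )
        for label in classes:
            term = str(rng.choice(lexicon.classes[label]))
            features.insert(int(rng.integers(0, len(features) + 1)), f"Severe {term}")
        synopsis = "Eyes:\n" + ";\n".join(f"   {f}" for f in features) + "\n"

        linked = rng.random() >= config.unlinked_fraction
        gene: str | None = None
        if linked:
            if used_genes and rng.random() < config.shared_gene_prob:
                gene = str(rng.choice(used_genes))
            elif fresh_i < len(pool):
                gene = pool[fresh_i]
                fresh_i += 1
            else:
                gene = str(rng.choice(pool))
            if gene not in used_genes:
                used_genes.append(gene)
            morbid_rows.append(f"Syndrome {i + 1}, {mim}\t{gene}\t{mim}")
        gene_by_mim[mim] = gene

        record_chunks.append(
            "*RECORD*\n"
            "*FIELD* NO\n"
            f"{mim}\n"
            "*FIELD* TI\n"
            f"#{mim} SYNDROME {i + 1}\n"
            "*FIELD* TX\n"
            f"A clinical entity with multiple features (entry {i + 1}).\n"
            "*FIELD* CS\n"
            f"{synopsis}"
        )

    geneid_rows = [
        f"{600000 + j:06d}\tgene\t{1000 + j}\t{g}\tENSG{j + 1:011d}"
        for j, g in enumerate(sorted(set(used_genes)))
    ]
    manifest = GroundTruthManifest(
        seed=int(seed),
        params=_config_dict(config),
        planted_classes=planted,
        gene_by_mim=gene_by_mim,
        unlinked_mim_ids=tuple(m for m, g in gene_by_mim.items() if g is None),
    )
    return (
        "\n".join(record_chunks) + "\n",
        "\n".join(morbid_rows) + ("\n" if morbid_rows else ""),
        "\n".join(geneid_rows) + ("\n" if geneid_rows else ""),
        manifest,
    )


# ---------------------------------------------------------------------------
# annotation catalog


def gen_annotation_catalog(
    config: SyntheticConfig,
    gene_symbols: Sequence[str],
    causal_genes: Sequence[str],
    seed: int,
) -> tuple[AnnotationCatalog, GroundTruthManifest]:
    """Random GMT-style terms plus one term enriched for the causal genes.

    The enriched term carries ``round(fold * |causal| * size / |universe|)``
    causal genes (capped at |causal|), i.e. the overlap a fold-enriched
    term would show in expectation when the causal set is the query.
    """
    causal = sorted(set(str(g) for g in causal_genes))
    base = list(dict.fromkeys(str(g) for g in gene_symbols))
    if not set(causal) <= set(base):
        raise ValueError("causal_genes must be a subset of gene_symbols")
    universe = list(base)
    i = 0
    while len(universe) < config.n_universe:
        i += 1
        universe.append(f"BKG{i:04d}")
    rng = np.random.default_rng([int(seed), 17])

    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    lo, hi = config.term_size_range
    enriched_id = "T0001"
    n_causal_in_term = 0
    for t in range(1, config.n_terms + 1):
        term_id = f"T{t:04d}"
        if term_id == enriched_id and causal:
            size = min(config.enriched_term_size, len(universe))
            m = int(round(config.enriched_fold * len(causal) * size / len(universe)))
            m = max(0, min(m, len(causal), size))
            n_causal_in_term = m
            chosen = list(rng.choice(causal, size=m, replace=False))
            others = [g for g in universe if g not in set(chosen)]
            chosen += list(rng.choice(others, size=size - m, replace=False))
            terms[term_id] = ("planted enriched process", tuple(chosen))
        else:
            size = int(rng.integers(lo, min(hi, len(universe)) + 1))
            terms[term_id] = (
                f"random process {t}",
                tuple(rng.choice(universe, size=size, replace=False)),
            )
    catalog = AnnotationCatalog(terms=terms, reference_genes=frozenset(universe))
    manifest = GroundTruthManifest(
        seed=int(seed),
        params=_config_dict(config),
        causal_genes=tuple(causal),
        enriched_term_id=enriched_id if causal else None,
        enriched_term_n_causal=n_causal_in_term,
    )
    return catalog, manifest


# ---------------------------------------------------------------------------
# bundle writer


def generate_bundle(
    config: SyntheticConfig,
    seed: int,
    outdir: str | Path,
    include_panel: bool = False,
) -> dict[str, Path]:
    """Write every pipeline input to ``outdir`` and return the path map.

    The panel TSV is large and only needed for gene-based testing, so it
    is written on request.  The merged manifest records all planted
    ground truth.
    """
    from . import gwas_io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci = gen_gene_loci(config, seed)
    panel = gen_reference_panel(config, seed) if include_panel else None
    variants, manifest = gen_summary_stats(config, loci, panel, seed)
    records, morbidmap, gene_ids, omim_manifest = gen_omim_fixture(
        config, seed, gene_symbols=[l.gene_symbol for l in loci]
    )
    catalog, cat_manifest = gen_annotation_catalog(
        config, [l.gene_symbol for l in loci], manifest.causal_genes, seed
    )
    manifest.planted_classes = omim_manifest.planted_classes
    manifest.gene_by_mim = omim_manifest.gene_by_mim
    manifest.unlinked_mim_ids = omim_manifest.unlinked_mim_ids
    manifest.enriched_term_id = cat_manifest.enriched_term_id
    manifest.enriched_term_n_causal = cat_manifest.enriched_term_n_causal

    paths = {
        "loci": outdir / "gene_loci.tsv",
        "summary_stats": outdir / "summary_stats.tsv",
        "omim_records": outdir / "omim_records.txt",
        "morbidmap": outdir / "morbidmap.txt",
        "gene_ids": outdir / "gene_ids.txt",
        "catalog": outdir / "catalog.gmt",
        "manifest": outdir / "manifest.json",
    }
    gwas_io.write_gene_loci(loci, paths["loci"])
    gwas_io.write_summary_stats(variants, paths["summary_stats"])
    paths["omim_records"].write_text(records, encoding="utf-8")
    paths["morbidmap"].write_text(morbidmap, encoding="utf-8")
    paths["gene_ids"].write_text(gene_ids, encoding="utf-8")
    catalog.to_gmt(paths["catalog"])
    manifest.to_json(paths["manifest"])
    if include_panel and panel is not None:
        paths["panel"] = outdir / "panel.tsv"
        gwas_io.write_panel_tsv(panel.to_frame(), paths["panel"])
    return paths
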