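"""End-to-end orchestration: mine -> windows -> select -> enrich -> test.

A single :class:`RunConfig` (constructible from a YAML file) drives the
full analysis: optional phenotype mining restricts the candidate loci,
windows are built around the (optionally autosome-only) loci, summary
statistics are MAF-filtered and captured, SNP-count enrichment is tested
at the nominal and experiment-wise levels, and — when the corresponding
inputs are configured — the LD-aware gene-based test and the
annotation-term overrepresentation screen run on top.  All outputs land
under a run directory with fixed names, and the JSON run report is
derived entirely from them.

``run_tophit_mode`` handles GWAS files that list only the hits below a
reporting threshold (no genome-wide rows): the binomial denominator then
comes from a configured count of reference variants within the candidate
windows, a deliberately conservative upper bound on the number of tests
actually performed inside the windows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import gwas_io
from .enrichment_stats import (
    EnrichmentResult,
    binomial_enrichment_test,
    count_exceedances,
    experiment_wise_threshold,
    qq_data,
)
from .gene_based import SimulationPlan, run_gene_tests
from .overrep import AnnotationCatalog, filter_highly_enriched, overrep_test
from .phenotype_mining import (
    TermLexicon,
    build_gene_sets,
    classify_refractive,
    link_genes,
    mining_report,
    parse_omim_records,
    write_gene_sets,
)
from .window_mapping import filter_autosomal, filter_maf, make_windows, select_variants

__all__ = ["RunConfig", "RunReport", "run_full", "run_tophit_mode"]

logger = logging.getLogger("omimgwas")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run."""

    outdir: str = "run"
    summary_stats: str | None = None
    gene_loci: str | None = None
    panel: str | None = None
    catalog: str | None = None
    omim_records: str | None = None
    morbidmap: str | None = None
    gene_ids: str | None = None
    lexicon: str | None = None
    gene_set_class: str = "any-myopia"
    flank_bp: int = 50_000
    min_maf: float = 0.01
    nominal_alpha: float = 0.05
    autosomal_only: bool = True
    tophit_threshold: float = 1.0e-4
    tophit_n_tests: int | None = None
    min_fold: float = 10.0
    overrep_alpha: float = 0.05
    sim_stages: tuple[int, ...] = (1_000, 10_000, 100_000, 1_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_maf", "nominal_alpha", "tophit_threshold", "overrep_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1) and not (name == "min_maf" and v == 0):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        self.sim_stages = tuple(int(s) for s in self.sim_stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _enrichment_dict(result: EnrichmentResult | None) -> dict | None:
    if result is None:
        return None
    return {
        "n_tests": result.n_tests,
        "threshold": result.threshold,
        "p0": result.p0,
        "observed": result.observed,
        "expected": result.expected,
        "expected_rounded": result.expected_rounded,
        "fold": result.fold,
        "p_binomial": result.p_binomial,
        "is_lower_bound": result.is_lower_bound,
    }


@dataclass
class RunReport:
    """Derived summary of a run; every number is recomputable from disk."""

    config: dict
    version: str = ""
    stages: dict[str, Any] = field(default_factory=dict)
    enrichment_nominal: dict | None = None
    enrichment_experiment_wise: dict | None = None
    gene_test: dict | None = None
    overrepresentation: dict | None = None
    elapsed_seconds: float = 0.0
    complete: bool = False
    error: dict | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, default=str)


def run_full(config: RunConfig) -> RunReport:
    """Execute every configured stage and write outputs + report.

    Idempotent for fixed inputs and seeds.  A stage failure aborts with
    :class:`StageError`; the partially written report is flagged
    incomplete and carries the machine-readable error record.
    """
    from . import __version__

    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)
    stage = "setup"
    try:
        # --- mine -----------------------------------------------------
        mined_genes: set[str] | None = None
        if config.omim_records:
            stage = "mine"
            logger.info("stage=mine seed=%s", config.seed)
            records = parse_omim_records(Path(config.omim_records))
            lexicon = (
                TermLexicon.from_yaml(config.lexicon)
                if config.lexicon
                else TermLexicon.default()
            )
            classifications = [classify_refractive(r, lexicon) for r in records]
            link_result = link_genes(
                classifications, config.morbidmap, config.gene_ids
            )
            gene_sets = build_gene_sets(link_result.links, classifications)
            write_gene_sets(gene_sets, outdir / "gene_sets.tsv")
            report.stages["mine"] = mining_report(
                records, classifications, link_result, gene_sets
            )
            with open(outdir / "mining_report.json", "w", encoding="utf-8") as fh:
                json.dump(report.stages["mine"], fh, indent=2)
            target = gene_sets.get(config.gene_set_class)
            mined_genes = set(target.gene_symbols) if target else set()

        # --- windows --------------------------------------------------
        stage = "windows"
        if not config.gene_loci:
            raise ValueError("gene_loci path is required")
        loci = gwas_io.read_gene_loci(config.gene_loci)
        if mined_genes is not None:
            loci = [l for l in loci if l.gene_symbol in mined_genes]
        excluded = []
        if config.autosomal_only:
            loci, excluded = filter_autosomal(loci)
        windows = make_windows(loci, config.flank_bp)
        report.stages["windows"] = {
            "n_loci": len(loci),
            "n_excluded_non_autosomal": len(excluded),
            "flank_bp": config.flank_bp,
        }
        logger.info("stage=windows n=%d excluded=%d", len(loci), len(excluded))

        # --- select ---------------------------------------------------
        stage = "select"
        if not config.summary_stats:
            raise ValueError("summary_stats path is required")
        variants = gwas_io.read_summary_stats(config.summary_stats)
        n_read = len(variants)
        variants, n_missing_maf = filter_maf(variants, config.min_maf)
        selection = select_variants(variants, windows)
        selection.flank_bp = config.flank_bp
        selection.global_variants.to_csv(
            outdir / "selected_variants.tsv", sep="\t", index=False
        )
        with open(outdir / "per_gene_index.json", "w", encoding="utf-8") as fh:
            json.dump(
                {g: [int(i) for i in idx] for g, idx in selection.per_gene.items()},
                fh,
            )
        report.stages["select"] = {
            "n_variants_read": n_read,
            "n_after_maf_filter": len(variants),
            "n_missing_maf_kept": n_missing_maf,
            "n_selected": selection.n_selected,
        }
        logger.info("stage=select kept=%d", selection.n_selected)

        # --- enrich ---------------------------------------------------
        stage = "enrich"
        n_sel = selection.n_selected
        if n_sel == 0:
            raise ValueError("no variants captured by the candidate windows")
        nominal = binomial_enrichment_test(
            count_exceedances(selection, config.nominal_alpha),
            n_sel,
            config.nominal_alpha,
        )
        ew_threshold = experiment_wise_threshold(n_sel)
        experiment_wise = binomial_enrichment_test(
            count_exceedances(selection, ew_threshold), n_sel, ew_threshold
        )
        report.enrichment_nominal = _enrichment_dict(nominal)
        report.enrichment_experiment_wise = _enrichment_dict(experiment_wise)
        qq = qq_data(selection.global_variants["p"].to_numpy())
        report.stages["enrich"] = {
            "nominal_exceedances": nominal.observed,
            "experiment_wise_threshold": ew_threshold,
            "experiment_wise_exceedances": experiment_wise.observed,
            "qq_envelope_coverage": qq.coverage(),
        }
        logger.info(
            "stage=enrich nominal=%d/%d p=%.3g", nominal.observed, n_sel, nominal.p_binomial
        )

        # --- gene-based test -------------------------------------------
        if config.panel:
            stage = "genetest"
            panel = gwas_io.read_panel_tsv(config.panel)
            plan = SimulationPlan(stages=config.sim_stages, master_seed=config.seed)
            summary = run_gene_tests(
                selection, panel, plan, alpha=config.nominal_alpha
            )
            summary.to_frame().to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)
            report.gene_test = {
                "n_genes": summary.n_genes,
                "n_significant": summary.n_significant,
                "alpha": summary.alpha,
                "omitted_genes": summary.omitted_genes,
                "n_missing_snps": summary.n_missing_snps,
                "enrichment": _enrichment_dict(summary.enrichment),
            }
            logger.info(
                "stage=genetest sig=%d/%d", summary.n_significant, summary.n_genes
            )

        # --- overrepresentation ----------------------------------------
        if config.catalog:
            stage = "overrep"
            catalog = AnnotationCatalog.from_gmt(config.catalog)
            query = (
                sorted(mined_genes)
                if mined_genes is not None
                else [l.gene_symbol for l in loci]
            )
            results = overrep_test(query, catalog)
            strong = filter_highly_enriched(
                results, config.min_fold, config.overrep_alpha
            )
            with open(outdir / "overrepresentation.tsv", "w", encoding="utf-8") as fh:
                fh.write(
                    "term_id\tterm_name\tn_term\tobserved\texpected\tfold\tp_raw\tp_corrected\n"
                )
                for r in results:
                    fh.write(
                        f"{r.term_id}\t{r.term_name}\t{r.n_term}\t{r.observed}\t"
                        f"{r.expected:.6g}\t{r.fold:.6g}\t{r.p_raw:.6g}\t{r.p_corrected:.6g}\n"
                    )
            report.overrepresentation = {
                "n_query_genes": len(query),
                "n_terms_tested": len(results),
                "n_highly_enriched": len(strong),
                "top_term": results[0].term_id if results else None,
                "highly_enriched_terms": [r.term_id for r in strong],
            }
            logger.info("stage=overrep strong=%d", len(strong))

        report.complete = True
    except Exception as exc:  # noqa: BLE001 - converted to a stage error record
        report.error = {"stage": stage, "message": str(exc), "type": type(exc).__name__}
        report.elapsed_seconds = time.time() - t0
        report.to_json(Path(config.outdir) / "run_report.json")
        raise StageError(stage, exc) from exc
    report.elapsed_seconds = time.time() - t0
    report.to_json(outdir / "run_report.json")
    return report


def run_tophit_mode(config: RunConfig) -> RunReport:
    """Enrichment for a top-hit-only GWAS file (reporting-threshold mode).

    The summary file lists only variants below the reporting threshold,
    so the observed count is the number of those hits inside the
    candidate windows, and the binomial null uses the configured
    ``tophit_n_tests`` — the count of reference-panel variants within
    windows, a conservative upper bound on the tests performed there.
    """
    from . import __version__

    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)
    stage = "config"
    try:
        if config.tophit_n_tests is None:
            raise ValueError("tophit_n_tests is required in top-hit mode")
        stage = "windows"
        loci = gwas_io.read_gene_loci(config.gene_loci)
        if config.autosomal_only:
            loci, _ = filter_autosomal(loci)
        windows = make_windows(loci, config.flank_bp)
        stage = "select"
        variants = gwas_io.read_summary_stats(config.summary_stats)
        over = variants["p"] >= config.tophit_threshold
        if over.any():
            raise ValueError(
                "top-hit mode expects only variants below the reporting threshold"
            )
        selection = select_variants(variants, windows)
        stage = "enrich"
        observed = count_exceedances(selection, config.tophit_threshold) if selection.n_selected else 0
        result = binomial_enrichment_test(
            observed, config.tophit_n_tests, config.tophit_threshold
        )
        report.stages["tophit"] = {
            "n_hits_in_file": len(variants),
            "n_hits_in_windows": selection.n_selected,
            "n_tests_bound": config.tophit_n_tests,
            "note": "denominator is a conservative upper bound from the reference variant list",
        }
        report.enrichment_nominal = _enrichment_dict(result)
        report.complete = True
    except Exception as exc:  # noqa: BLE001
        report.error = {"stage": stage, "message": str(exc), "type": type(exc).__name__}
        report.to_json(outdir / "run_report.json")
        raise StageError(stage, exc) from exc
    report.elapsed_seconds = time.time() - t0
    report.to_json(outdir / "run_report.json")
    return report
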