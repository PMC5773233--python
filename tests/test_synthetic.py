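"""Generators: loci placement, panel LD, summary statistics, fixtures."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from omimgwas.phenotype_mining import classify_refractive, parse_omim_records
from omimgwas.synthetic import (
    SyntheticConfig,
    gen_annotation_catalog,
    gen_gene_loci,
    gen_omim_fixture,
    gen_reference_panel,
    gen_summary_stats,
    gen_variant_grid,
)
from omimgwas.window_mapping import make_windows, select_variants


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(ld_rho=1.0)
        with pytest.raises(ValueError):
            SyntheticConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SyntheticConfig(effect_lambda=-1)
        with pytest.raises(ValueError):
            SyntheticConfig(n_genes=0)


class TestGeneLoci:
    def test_spans_non_overlapping_and_in_range(self, small_config):
        loci = gen_gene_loci(small_config, seed=2)
        assert len(loci) == small_config.n_genes
        lo, hi = small_config.gene_length_range
        by_chrom: dict[str, list] = {}
        for locus in loci:
            assert lo <= locus.tx_end - locus.tx_start + 1 <= hi
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        for group in by_chrom.values():
            group.sort(key=lambda l: l.tx_start)
            for a, b in zip(group, group[1:]):
                assert a.tx_end < b.tx_start

    def test_deterministic_per_seed(self, small_config):
        assert gen_gene_loci(small_config, 9) == gen_gene_loci(small_config, 9)
        assert gen_gene_loci(small_config, 9) != gen_gene_loci(small_config, 10)

    def test_overfull_chromosome_rejected(self):
        config = SyntheticConfig(
            chromosome_length_bp=100_000, n_genes=10, gene_length_range=(50_000, 60_000)
        )
        with pytest.raises(ValueError, match="too short"):
            gen_gene_loci(config, 1)


class TestVariantGridAndPanel:
    def test_grid_structure(self, small_config):
        grid = gen_variant_grid(small_config, seed=4)
        assert grid.n == small_config.n_variants
        lo, hi = small_config.maf_range
        assert grid.maf.min() >= lo and grid.maf.max() <= hi
        for chrom in np.unique(grid.chromosomes):
            pos = grid.positions[grid.chromosomes == chrom]
            assert np.all(np.diff(pos) > 0)
        # blocks never span chromosomes and respect the configured size
        for block in grid.block_slices():
            assert block.stop - block.start <= small_config.ld_block_size
            assert len(set(grid.chromosomes[block])) == 1

    def test_panel_maf_matches_drawn_maf(self):
        config = SyntheticConfig(
            n_chromosomes=1,
            chromosome_length_bp=1_000_000,
            n_genes=2,
            n_variants=150,
            n_reference_samples=10_000,
        )
        panel = gen_reference_panel(config, seed=6)
        assert np.abs(panel.empirical_maf() - panel.grid.maf).max() < 0.03

    def test_rho_zero_gives_independent_dosages(self):
        config = SyntheticConfig(
            n_chromosomes=1,
            chromosome_length_bp=1_000_000,
            n_genes=2,
            n_variants=60,
            n_reference_samples=10_000,
            ld_rho=0.0,
        )
        panel = gen_reference_panel(config, seed=8)
        d = panel.dosages.astype(float)
        r = np.corrcoef(d, rowvar=False)
        assert np.abs(r[~np.eye(60, dtype=bool)]).max() < 0.05

    def test_adjacent_dosage_ld_matches_threshold_model(self):
        # dichotomizing a latent Gaussian attenuates correlation; compare
        # the realized adjacent-pair dosage r against the analytic value
        # for the threshold model at each pair's MAFs
        from scipy.stats import multivariate_normal

        config = SyntheticConfig(
            n_chromosomes=1,
            chromosome_length_bp=1_000_000,
            n_genes=2,
            n_variants=40,
            n_reference_samples=10_000,
            ld_rho=0.8,
        )
        panel = gen_reference_panel(config, seed=9)
        d = panel.dosages.astype(float)
        grid = panel.grid
        t = stats.norm.isf(grid.maf)
        observed, predicted = [], []
        for i in range(39):
            if grid.block_ids[i] != grid.block_ids[i + 1]:
                continue
            observed.append(np.corrcoef(d[:, i], d[:, i + 1])[0, 1])
            mvn = multivariate_normal(
                mean=[0, 0], cov=[[1, config.ld_rho], [config.ld_rho, 1]]
            )
            p11 = mvn.cdf([-t[i], -t[i + 1]])  # P(z_i > t_i, z_j > t_j) by symmetry
            mi, mj = grid.maf[i], grid.maf[i + 1]
            predicted.append(
                (p11 - mi * mj) / np.sqrt(mi * (1 - mi) * mj * (1 - mj))
            )
        assert np.mean(np.abs(np.array(observed) - np.array(predicted))) < 0.05

    def test_panel_deterministic(self, small_config):
        config = dataclasses.replace(small_config, n_reference_samples=100, n_variants=400)
        a = gen_reference_panel(config, 3)
        b = gen_reference_panel(config, 3)
        assert np.array_equal(a.dosages, b.dosages)


class TestSummaryStats:
    def test_null_calibration(self, small_config):
        config = dataclasses.replace(small_config, effect_lambda=0.0)
        loci = gen_gene_loci(config, 1)
        variants, manifest = gen_summary_stats(config, loci, None, 1)
        assert manifest.causal_genes == ()
        frac = float((variants["p"] < 0.05).mean())
        sigma = np.sqrt(0.05 * 0.95 / len(variants))
        assert abs(frac - 0.05) < 3 * sigma

    def test_causal_spike_lands_in_window(self, small_config):
        loci = gen_gene_loci(small_config, 2)
        variants, manifest = gen_summary_stats(small_config, loci, None, 2)
        assert len(manifest.causal_genes) == round(
            small_config.causal_gene_fraction * small_config.n_genes
        )
        by_symbol = {l.gene_symbol: l for l in loci}
        lookup = variants.set_index("snp")
        for gene, snp in manifest.causal_snp_by_gene.items():
            locus = by_symbol[gene]
            row = lookup.loc[snp]
            assert row["chr"] == locus.chromosome
            assert (
                locus.tx_start - small_config.flank_bp
                <= row["pos"]
                <= locus.tx_end + small_config.flank_bp
            )

    def test_causal_snps_carry_strong_signal_on_average(self, small_config):
        neglogs = []
        for seed in range(10):
            loci = gen_gene_loci(small_config, seed)
            variants, manifest = gen_summary_stats(small_config, loci, None, seed)
            lookup = variants.set_index("snp")
            for snp in manifest.causal_snp_by_gene.values():
                neglogs.append(-np.log10(lookup.loc[snp, "p"]))
        # expected -log10 p at |z| ~ 6 is ~9.9; the mean over draws is high
        assert np.mean(neglogs) > 5.0

    def test_pure_function_of_seed(self, small_config):
        loci = gen_gene_loci(small_config, 5)
        a, _ = gen_summary_stats(small_config, loci, None, 5)
        b, _ = gen_summary_stats(small_config, loci, None, 5)
        assert a.equals(b)


class TestOmimFixture:
    def test_round_trip_recovers_planted_classes(self, small_config, lexicon):
        text, _, _, manifest = gen_omim_fixture(small_config, seed=13)
        records = parse_omim_records(text)
        assert len(records) == small_config.n_omim_records
        for record in records:
            found = classify_refractive(record, lexicon).classes_found
            assert set(found) == set(manifest.planted_classes[record.mim_id])

    def test_unlinked_fraction_reflected_in_tables(self, small_config):
        _, morbidmap, gene_ids, manifest = gen_omim_fixture(small_config, seed=14)
        linked = [m for m, g in manifest.gene_by_mim.items() if g is not None]
        assert len(linked) + len(manifest.unlinked_mim_ids) == small_config.n_omim_records
        assert len(morbidmap.strip().splitlines()) == len(linked)
        listed = {line.split("\t")[3] for line in gene_ids.strip().splitlines()}
        assert listed == {g for g in manifest.gene_by_mim.values() if g is not None}

    def test_zero_records(self):
        config = SyntheticConfig(n_omim_records=0)
        text, morbidmap, gene_ids, manifest = gen_omim_fixture(config, seed=1)
        assert parse_omim_records(text) == []
        assert manifest.planted_classes == {}


class TestAnnotationCatalog:
    def test_planted_term_contains_configured_overlap(self, small_config):
        genes = [f"G{i:03d}" for i in range(100)]
        causal = genes[:10]
        catalog, manifest = gen_annotation_catalog(small_config, genes, causal, seed=3)
        assert len(catalog.terms) == small_config.n_terms
        _, term_genes = catalog.terms[manifest.enriched_term_id]
        overlap = len(set(term_genes) & set(causal))
        expected = round(
            small_config.enriched_fold
            * len(causal)
            * small_config.enriched_term_size
            / small_config.n_universe
        )
        assert overlap == manifest.enriched_term_n_causal == expected
        for _, (name, term) in catalog.terms.items():
            assert len(term) == len(set(term))

    def test_causal_outside_universe_rejected(self, small_config):
        with pytest.raises(ValueError):
            gen_annotation_catalog(small_config, ["A"], ["B"], seed=1)


class TestEndToEndGeneration:
    def test_windows_capture_more_signal_than_background(self, small_config):
        """Enriched-regime sanity: in-window variants carry excess signal."""
        loci = gen_gene_loci(small_config, 17)
        variants, manifest = gen_summary_stats(small_config, loci, None, 17)
        sel = select_variants(variants, make_windows(loci, small_config.flank_bp))
        inside = sel.global_variants["p"].to_numpy()
        frac_inside = float((inside < 0.05).mean())
        frac_overall = float((variants["p"] < 0.05).mean())
        assert frac_inside > frac_overall
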