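# Methods

## Phenotype mining

Records are parsed from the classic `*RECORD*` / `*FIELD*` flat-file
dialect (identifier under `NO`, title under `TI`, clinical synopsis
under `CS`). Classification scans only the clinical synopsis with a
term lexicon mapping four refractive classes — myopia, hyperopia,
astigmatism, other ametropia — to whole-word, case-insensitive search
terms. Word boundaries fall at any non-letter character except `-`,
which joins letters: "near-sighted" is one word, and neither
"amyopiaX" nor "pre-myopia" contains the word "myopia". The exact
published search-term table is not available, so the shipped lexicon
(`src/omimgwas/data/lexicon.yaml`) is a reasonable default covering
the common clinical spellings, and is deliberately an editable
configuration file: drop in a replacement via `TermLexicon.from_yaml`
or the pipeline's `lexicon` path. Titles are not scanned by default;
clinical synopses are where refractive features are listed.

Gene linkage uses morbidmap-style (phenotype / gene symbols / id) and
gene-id (id / type / entrez / symbol / ensembl) tables. Phenotypes
with a refractive class but no gene row go to a skipped list — the
analog of catalog entities with no identified causal gene. Gene
identity for deduplication is the approved symbol. Per class the
package emits an inclusive `any-<class>` set, the union
`all-ametropia`, and an exclusive `<class>-only` set (phenotypes whose
only refractive feature is that class); the duplicate count collapsed
per set equals the sum over genes of (links − 1).

## Windows and variant capture

Coordinates are 1-based closed intervals everywhere; BED input
(0-based half-open) is converted at the reader. A gene's capture
window is `[max(1, tx_start − flank), tx_end + flank]` with a 50 kb
default flank — the scale at which most regulatory GWAS signal sits
relative to its target gene. Chromosome labels are normalized (strip
`chr`, uppercase, `23` → X); X/Y/MT loci can be partitioned out, since
many meta-analyses exclude them. The MAF filter keeps variants with
MAF strictly above the cutoff (default 0.01) and retains
missing-frequency variants with a warning tally.

Selection keeps two views deliberately: the **global** list is
deduplicated (a variant near two candidate genes counts once in
genome-wide exceedance counts, matching how a single in-window SNP
list is reported), while **per-gene** lists retain shared variants,
because the gene-based test scores each gene on everything in its own
window.

## SNP-count enrichment

With N selected variants and a cutoff α, the observed exceedance count
k (strict `p < α`) is tested against Binomial(N, p₀) via the exact
one-sided upper tail, computed by `scipy`'s survival function and, when
that underflows, by direct log-space summation of pmf terms; a tail
below the smallest positive double is floored there and flagged as a
"less than" bound, so results print as bounds rather than zeros. Two
cutoffs are always computed: the nominal level (p₀ = α) and the
experiment-wise level p₀ = 1/N exactly (not a rounded printed value —
using the exact reciprocal is what reproduces the published
15-of-24,554 tail of 3.0×10⁻¹³; the same quantity has been printed
elsewhere rounded both to 4.4×10⁻⁵ and 4.1×10⁻⁵, and 1/24,554 =
4.07×10⁻⁵ is what the implementation returns).

**Which test decides.** The pipeline reports both, but its primary
null-rejection statistic is the **experiment-wise** count test. The
binomial model assumes independent exceedances, and at moderate
thresholds (α = 0.05) local LD clusters exceedances, overdispersing
the count roughly two-fold and making the nominal-level binomial test
anti-conservative (about 10% type-I at α = 0.05 under the synthetic
null). Exceedances of the extreme 1/N threshold are asymptotically
independent under a Gaussian dependence structure (the Gaussian copula
has no tail dependence), so the experiment-wise count is nearly
binomial even under strong LD — measured type-I ≈ 2% at α = 0.05 on
null synthetic data — while retaining essentially full power against
the planted enrichment. The nominal-level count remains in every
report as the descriptive headline (observed vs expected, fold).

QQ data pair the sorted observed p-values with expected quantiles
i/(N+1) and pointwise 95% envelopes from Beta(i, N+1−i) — the law of
the i-th of N uniform order statistics. Envelopes are pointwise, not
simultaneous bands: each rank's interval covers its order statistic
with 95% probability, and about 5% of ranks fall outside under the
null. Manhattan data add cumulative genome coordinates and both guide
lines.

## Gene-based test

Per gene, T = Σⱼ Qχ²₍₁₎(pⱼ) over the window SNPs (the χ²(1) upper-tail
inverse; equivalently z² for two-sided z-tests — signed effects are
reduced to p-values first). The null distribution of T under LD is
simulated: y ~ MVN(0, R) with R the product-moment correlation of
panel dosages, T\* = ‖y‖², and p = (#{T\* ≥ T} + 1)/(n + 1). The +1
smoothing keeps p in (0, 1] with floor 1/(n + 1). R is repaired to
positive semi-definiteness by eigenvalue clipping at 10⁻⁸ and
re-normalization to unit diagonal; the factorization is computed once
per gene and cached. Monomorphic panel SNPs raise an error naming the
SNP at the estimation level and are dropped with a tally by the
pipeline-level runner, as are summary SNPs absent from the panel.

Simulation effort follows a staged plan (defaults 10³ → 10⁴ → 10⁵ →
10⁶ cumulative draws), escalating while fewer than ten null draws have
reached T — precision concentrates on the significant genes.
Reduced plans (e.g. two stages of 10³/2×10⁴) are used in the test
suite and pipeline demonstrations, where per-gene p-value resolution
below ~10⁻⁴ is not needed; the plan is a run-time parameter. Each
gene's random stream is keyed by a CRC-32 of its symbol plus the master
seed, so per-gene results are reproducible and independent of gene
ordering. The set-level summary counts genes with p < 0.05 and feeds
that count to the binomial enrichment test with p₀ = 0.05.

## Term overrepresentation

The default model is the classic binomial overrepresentation test:
with n query genes mapped into the universe and a term covering
fraction q of the universe, p_raw = P(X ≥ observed), X ~ Binomial(n, q),
expected = n·q, fold = observed/expected. A hypergeometric variant
(sampling without replacement) is available behind a flag. Terms with
zero query hits are not tested and do not enter the Bonferroni
denominator (the behavior of typical overrepresentation tools; a
switch includes them). The reporting filter keeps terms with fold ≥ 10
and corrected p < 0.05, sorted by fold. The subsample sensitivity
analysis re-runs the filtered screen on random subsets of the query
set and reports the mean retained-term count per subsample size.

## Synthetic data

Every generator is a pure function of (config, seed); all streams are
derived from `numpy` seed sequences so components are independently
reproducible.

- **Gene loci**: non-overlapping spans, lengths uniform in 5–100 kb,
  placed uniformly per chromosome.
- **Variant grid**: uniform unique positions, MAF uniform in
  (0.01, 0.5], consecutive LD blocks of 20 SNPs within chromosomes.
- **Reference panel**: per individual, two latent AR(1) Gaussian
  haplotype fields per block (corr ρ^|i−j|, ρ = 0.7), thresholded at
  each SNP's allele frequency and summed to 0/1/2 dosages. Note that
  dichotomizing a latent Gaussian attenuates product-moment
  correlation: adjacent-pair dosage r is roughly half the latent ρ
  (the test suite checks the realized dosage LD against the analytic
  threshold-model value). Consequently panel-estimated LD understates
  the latent correlation used to draw summary z-scores — a real-data
  analog is LD panels mismatched to the GWAS sample, and a known
  limitation of the synthetic end-to-end setup.
- **Summary statistics**: per block, z ~ MVN(μ, Σ) with Σ the block's
  latent AR(1) correlation; under the enriched regime a causal SNP is
  chosen near each causal gene's midpoint and μⱼ = λ·r_{j,c}
  (LD-propagated non-centrality, λ = 6 ≈ a genome-wide-significant
  association); p = two-sided normal tail. Drawing z directly from the
  LD-implied MVN gives the same sampling distribution as simulating
  phenotypes and regressing, at a small fraction of the cost.
- **Record fixtures**: each record receives one class from the
  configured mix (60/20/10/10% across myopia/hyperopia/astigmatism/
  other, a second class with probability 0.15), realized as lexicon
  terms inside an otherwise term-free synopsis; 25% of records get no
  gene link and 8% of links reuse an earlier gene, so the skipped list
  and deduplication have work to do.
- **Annotation catalog**: 100 random terms of 10–60 genes over a
  1,000-gene universe; one planted term of 60 genes carries
  `round(fold · |causal| · size / |universe|)` causal genes — the
  overlap a ten-fold-enriched term shows in expectation when the
  causal set is the query. With the default geometry that is 6 of 10
  causal genes, a decisively detectable enrichment; a planted overlap
  of a single gene (as arises for very small terms) is statistically
  indistinguishable from background, which is why the planted term is
  given a large size.

**Scale calibration.** Defaults are 2 chromosomes × 100 Mb, 100 genes,
2×10⁴ variants, 2×10³ panel samples. The genome size was chosen so the
±50 kb windows cover well under a tenth of the genome: in a real
candidate-gene scan the windows are a sparse subset of the GWAS
(≈25 k of 2.5 M variants), and a toy genome small enough for windows
to swallow most variants leaves no background against which enrichment
is defined. The LD parameters (ρ = 0.7, blocks of 20 at ~10 kb
spacing) were fixed by a pre-registered design scan so that the
generator's two regimes exhibit the intended operating
characteristics: under λ = 0 the pipeline's primary test rejects at
about its nominal rate, and under λ = 6 with 10/100 causal genes it
rejects at P < 0.001 essentially always. These defaults are the study
conditions of the validation suite and are not tuned per test.

What the synthetic data does **not** emulate: realistic human LD maps
(block boundaries are abrupt, correlation is stationary AR(1)),
allele-frequency/LD coupling, imputation error, population structure,
or polygenic background outside the planted genes. Passing the
end-to-end checks therefore demonstrates correctness of the machinery
and calibration under the stated dependence model, not performance on
real GWAS data.

## Pipeline

`run_full` executes mine → windows → select → enrich → gene tests →
overrepresentation, skipping stages whose inputs are not configured,
and writes every stage product plus a JSON run report that is entirely
recomputable from the on-disk outputs. Reruns with the same config are
byte-identical. A stage failure aborts with the stage name and leaves
a machine-readable error record flagged incomplete.

Top-hit mode handles GWAS releases that publish only variants below a
reporting threshold (default 10⁻⁴). The observed count is the number
of published hits inside the windows; the binomial denominator must be
supplied as the count of reference-panel variants within the windows.
That denominator is deliberately an overestimate of the number of
tests actually performed in the windows, making the resulting
enrichment p-value a conservative upper bound — the report labels it
as such.

## Numerical choices

- Exceedance counting is strict (`p < α`); MAF filtering is strict
  (`maf > cutoff`).
- Expected counts round half away from zero (24,554 × 0.05 = 1227.7 →
  1228).
- Binomial tails: exact; log-space summation on underflow; floored at
  the smallest positive double with a bound flag.
- Gene statistic: p-values of exactly 0 or 1 are clamped into the open
  interval with a warning (they arise from rounding in summary files).
- LD repair: eigenvalue clip at 10⁻⁸, re-normalize diagonal; Cholesky
  with eigen-factor fallback.
- Ties in overrepresentation ranking break by raw p, then fold, then
  term id; selection ordering is (chromosome, position, variant id).

## Known limitations

- The binomial SNP-count test ignores LD by construction; its
  nominal-level variant is anti-conservative under strong LD (see
  above) and is reported descriptively, not decisively.
- The gene-based null assumes the panel LD matches the GWAS sample's
  LD; mismatch (including the synthetic attenuation noted above)
  shifts per-gene calibration.
- Bonferroni across tested terms is conservative under correlated,
  hierarchical annotations; no graph-aware propagation is attempted.
- The mining lexicon is a default, not the published table; results on
  real records depend on supplying the intended vocabulary.
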