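"""Annotation-term overrepresentation testing for gene sets.

Classic catalog screening: given a query gene set and an annotation
catalog (GO-style biological-process terms over a reference universe),
ask for each term whether the query contains more of its genes than a
random draw of the same size would.  The default model is the one-sided
binomial used by the classic PANTHER-style overrepresentation test:
with n = |query ∩ universe| and per-gene hit probability
q = |term| / |universe|, the raw p-value is P(X >= observed) for
X ~ Binomial(n, q).  A hypergeometric (Fisher-style, sampling without
replacement) alternative is available behind a flag.  Raw p-values are
Bonferroni-corrected across the terms actually tested (terms with zero
query hits are skipped and do not enter the correction; pass
``test_empty=True`` to include them).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnnotationCatalog",
    "OverrepResult",
    "overrep_test",
    "filter_highly_enriched",
    "subsample_sensitivity",
]


@dataclass
class AnnotationCatalog:
    """Term annotations over a reference gene universe.

    ``terms`` maps term id -> (term name, annotated gene symbols);
    every annotated gene belongs to ``reference_genes`` and term lists
    are deduplicated.
    """

    terms: dict[str, tuple[str, tuple[str, ...]]]
    reference_genes: frozenset[str]

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, tuple[str, ...]]] = {}
        for term_id, (name, genes) in self.terms.items():
            unique = tuple(dict.fromkeys(genes))
            missing = [g for g in unique if g not in self.reference_genes]
            if missing:
                raise ValueError(
                    f"term {term_id}: genes not in universe (e.g. {missing[0]!r})"
                )
            cleaned[term_id] = (name, unique)
        self.terms = cleaned

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "AnnotationCatalog":
        """Read a GMT file (term, description, genes...), one term per line.

        With no explicit universe, the union of all term genes is used.
        """
        terms: dict[str, tuple[str, tuple[str, ...]]] = {}
        union: set[str] = set()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            term_id, name, genes = parts[0], parts[1], tuple(g for g in parts[2:] if g)
            terms[term_id] = (name, genes)
            union.update(genes)
        ref = frozenset(universe) if universe is not None else frozenset(union)
        return cls(terms=terms, reference_genes=ref)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for term_id, (name, genes) in self.terms.items():
                handle.write("\t".join([term_id, name, *genes]) + "\n")


@dataclass(frozen=True)
class OverrepResult:
    """One term's overrepresentation outcome within a query set."""

    term_id: str
    term_name: str
    n_term: int
    observed: int
    expected: float
    fold: float
    p_raw: float
    p_corrected: float


def overrep_test(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    method: str = "binomial",
    test_empty: bool = False,
) -> list[OverrepResult]:
    """Test every catalog term for overrepresentation in the query set.

    Query genes outside the universe are dropped before testing (the
    tally is recoverable as ``len(query) - n`` from the inputs).
    Results are sorted by raw p-value, then fold, then term id.
    """
    if method not in ("binomial", "hypergeometric"):
        raise ValueError("method must be 'binomial' or 'hypergeometric'")
    universe = catalog.reference_genes
    if not universe:
        raise ValueError("annotation catalog has an empty universe")
    mapped = frozenset(query) & universe
    n = len(mapped)
    m = len(universe)
    tested: list[tuple[str, str, int, int]] = []
    for term_id, (name, genes) in catalog.terms.items():
        observed = len(mapped & frozenset(genes))
        if observed == 0 and not test_empty:
            continue
        tested.append((term_id, name, len(genes), observed))
    n_tested = len(tested)
    results: list[OverrepResult] = []
    for term_id, name, n_term, observed in tested:
        q = n_term / m
        expected = n * q
        if method == "binomial":
            p_raw = float(stats.binom.sf(observed - 1, n, q)) if n else 1.0
        else:
            p_raw = float(stats.hypergeom.sf(observed - 1, m, n_term, n)) if n else 1.0
        p_raw = min(max(p_raw, 0.0), 1.0) or np.nextafter(0, 1)
        fold = observed / expected if expected > 0 else (np.inf if observed else 0.0)
        results.append(
            OverrepResult(
                term_id=term_id,
                term_name=name,
                n_term=n_term,
                observed=observed,
                expected=expected,
                fold=fold,
                p_raw=p_raw,
                p_corrected=min(1.0, p_raw * n_tested),
            )
        )
    results.sort(key=lambda r: (r.p_raw, -r.fold, r.term_id))
    return results


def filter_highly_enriched(
    results: Sequence[OverrepResult], min_fold: float = 10.0, alpha: float = 0.05
) -> list[OverrepResult]:
    """Keep strongly overrepresented terms, sorted by fold descending.

    A term passes with fold >= ``min_fold`` and corrected p < ``alpha``
    (the ">= 10-fold and significant" reporting convention).
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    kept = [r for r in results if r.fold >= min_fold and r.p_corrected < alpha]
    kept.sort(key=lambda r: (-r.fold, r.p_corrected, r.term_id))
    return kept


def subsample_sensitivity(
    gene_set: Iterable[str],
    subsample_size: int,
    catalog: AnnotationCatalog,
    n_reps: int = 100,
    seed: int = 0,
    min_fold: float = 10.0,
    alpha: float = 0.05,
    method: str = "binomial",
) -> tuple[float, list[int]]:
    """How stable is the significant-term count under random subsampling?

    Draws ``n_reps`` uniform subsets of ``subsample_size`` genes without
    replacement, reruns the overrepresentation screen with the
    high-enrichment filter, and returns the mean count of retained terms
    together with the per-replicate counts.
    """
    genes = sorted(set(gene_set))
    if subsample_size > len(genes):
        raise ValueError("subsample_size exceeds the gene set size")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts: list[int] = []
    for _ in range(n_reps):
        sub = rng.choice(genes, size=subsample_size, replace=False)
        results = overrep_test(sub, catalog, method=method)
        counts.append(len(filter_highly_enriched(results, min_fold, alpha)))
    return float(np.mean(counts)), counts
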