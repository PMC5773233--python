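"""Exceedance counts, binomial enrichment tests, and QQ/Manhattan data.

The core question: do more variants in candidate-gene windows reach a
p-value threshold than chance predicts?  Under the null, each of the N
selected variants exceeds a cutoff alpha independently with probability
p0 (p0 = alpha for a nominal cutoff, or 1/N for the experiment-wise
cutoff at which a single exceedance is expected).  The observed count k
is then compared with Binomial(N, p0) via the one-sided upper tail
P(K >= k).  The binomial ignores local LD between variants, so it is an
enrichment screen rather than a calibrated genome-wide test; the
LD-aware per-gene analysis lives in :mod:`omimgwas.gene_based`.

QQ data carry pointwise 95% null envelopes from the order-statistic law
of uniforms: the i-th smallest of N uniform p-values follows
Beta(i, N + 1 - i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .window_mapping import WindowSelection, chromosome_sort_key

__all__ = [
    "EnrichmentResult",
    "QQData",
    "expected_count",
    "experiment_wise_threshold",
    "binomial_enrichment_test",
    "count_exceedances",
    "qq_data",
    "manhattan_data",
]

#: Smallest positive subnormal double; the reporting floor for p-values.
_TINY = 5e-324


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of a one-sided binomial exceedance test.

    ``p_binomial`` is P(K >= observed) for K ~ Binomial(n_tests, p0).
    When the tail underflows double precision the value is floored at
    the smallest positive double and ``is_lower_bound`` is set, so the
    result prints as a "<" bound rather than an impossible zero.
    """

    n_tests: int
    threshold: float
    p0: float
    observed: int
    expected: float
    expected_rounded: int
    fold: float
    p_binomial: float
    is_lower_bound: bool = False

    def __str__(self) -> str:
        rel = "<" if self.is_lower_bound else "="
        return (
            f"{self.observed}/{self.n_tests} at p<{self.threshold:g} "
            f"(expected {self.expected:.4g}, fold {self.fold:.3g}, "
            f"binomial P {rel} {self.p_binomial:.2g})"
        )


def expected_count(n_tests: int, p0: float) -> tuple[float, int]:
    """Null expectation ``n_tests * p0`` and its integer rounding.

    Rounding is half away from zero, matching how expected counts are
    conventionally quoted (e.g. 24,554 x 0.05 = 1227.7 -> 1228).
    """
    if n_tests < 0:
        raise ValueError("n_tests must be non-negative")
    if not (0 <= p0 <= 1):
        raise ValueError("p0 must be in [0, 1]")
    expected = n_tests * p0
    return expected, int(math.floor(expected + 0.5))


def experiment_wise_threshold(n_tests: int) -> float:
    """The per-test cutoff 1/N at which one null exceedance is expected."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 1.0 / n_tests


def _log_tail(observed: int, n: int, p0: float) -> float:
    """log P(K >= observed) by direct pmf summation in log space."""
    dist = stats.binom(n, p0)
    logs: list[float] = []
    k = observed
    chunk = 512
    while k <= n:
        hi = min(n, k + chunk - 1)
        ks = np.arange(k, hi + 1)
        lp = dist.logpmf(ks)
        logs.append(float(logsumexp(lp)))
        # Terms beyond the mode decay geometrically; stop once a whole
        # chunk contributes nothing at double precision.
        if hi >= n or (lp[-1] < max(logs) - 60 and ks[-1] > n * p0):
            break
        k = hi + 1
    return float(logsumexp(logs))


def binomial_enrichment_test(observed: int, n_tests: int, p0: float,
                             threshold: float | None = None) -> EnrichmentResult:
    """One-sided binomial test of an exceedance count against its null.

    Exact upper tail P(K >= observed); computed in log space when the
    standard survival function underflows, and floored at the smallest
    positive double (with ``is_lower_bound=True``) if even the log-space
    sum underflows.
    """
    if not (0 <= observed <= n_tests):
        raise ValueError("observed must be in [0, n_tests]")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    expected, rounded = expected_count(n_tests, p0)
    p = float(stats.binom.sf(observed - 1, n_tests, p0))
    lower_bound = False
    if p == 0.0:
        log_p = _log_tail(observed, n_tests, p0)
        p = float(np.exp(log_p))
        if p == 0.0:
            p = _TINY
            lower_bound = True
    p = min(p, 1.0)
    fold = (observed / expected) if expected > 0 else (math.inf if observed else 0.0)
    return EnrichmentResult(
        n_tests=n_tests,
        threshold=p0 if threshold is None else threshold,
        p0=p0,
        observed=observed,
        expected=expected,
        expected_rounded=rounded,
        fold=fold,
        p_binomial=p,
        is_lower_bound=lower_bound,
    )


def count_exceedances(selection: WindowSelection, threshold: float) -> int:
    """Count deduplicated in-window variants with p strictly below threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if selection.n_selected == 0:
        return 0
    p = selection.global_variants["p"].to_numpy(dtype=float)
    return int((p < threshold).sum())


@dataclass
class QQData:
    """Sorted observed p-values with null quantiles and a 95% envelope.

    ``expected[i] = (i+1)/(N+1)``; the envelope is the pointwise 2.5%
    and 97.5% quantiles of Beta(i+1, N - i), the law of the (i+1)-th
    uniform order statistic.
    """

    observed: np.ndarray
    expected: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def neglog10_observed(self) -> np.ndarray:
        return -np.log10(self.observed)

    @property
    def neglog10_expected(self) -> np.ndarray:
        return -np.log10(self.expected)

    @property
    def neglog10_lower(self) -> np.ndarray:
        return -np.log10(self.upper)

    @property
    def neglog10_upper(self) -> np.ndarray:
        return -np.log10(self.lower)

    def coverage(self) -> float:
        """Fraction of ranks whose observed value sits inside the envelope."""
        inside = (self.observed >= self.lower) & (self.observed <= self.upper)
        return float(inside.mean())


def qq_data(p_values: Sequence[float] | np.ndarray) -> QQData:
    """Expected-vs-observed quantiles with Beta order-statistic envelopes."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    obs = np.sort(p)
    ranks = np.arange(1, n + 1)
    expected = ranks / (n + 1.0)
    lower = stats.beta.ppf(0.025, ranks, n + 1 - ranks)
    upper = stats.beta.ppf(0.975, ranks, n + 1 - ranks)
    return QQData(observed=obs, expected=expected, lower=lower, upper=upper)


def manhattan_data(
    selection: WindowSelection,
    nominal_alpha: float = 0.05,
    experiment_wise: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-variant plot rows with cumulative genome coordinates.

    Returns ``(table, metadata)``: the table has one row per selected
    variant (chromosome, position, cumulative position, -log10 p, source
    genes), and metadata carries the nominal and experiment-wise guide
    lines plus per-chromosome offsets for axis labeling.
    """
    if selection.n_selected == 0:
        raise ValueError("selection is empty")
    df = selection.global_variants.copy()
    gene_by_row: dict[int, list[str]] = {}
    for gene, idx in selection.per_gene.items():
        for i in idx:
            gene_by_row.setdefault(int(i), []).append(gene)
    df["gene_symbol"] = [
        ",".join(sorted(gene_by_row.get(int(i), []))) for i in df.index.to_numpy()
    ]
    df["chr"] = df["chr"].astype(str)
    chroms = sorted(df["chr"].unique(), key=chromosome_sort_key)
    offsets: dict[str, int] = {}
    running = 0
    for c in chroms:
        offsets[c] = running
        running += int(df.loc[df["chr"] == c, "pos"].max()) + 1
    df["cum_pos"] = df["pos"].to_numpy() + df["chr"].map(offsets).to_numpy()
    df["neglog10_p"] = -np.log10(df["p"].to_numpy(dtype=float))
    if experiment_wise is None:
        experiment_wise = experiment_wise_threshold(selection.n_selected)
    meta = {
        "nominal_alpha": float(nominal_alpha),
        "experiment_wise_threshold": float(experiment_wise),
        "chromosome_offsets": offsets,
        "n_variants": selection.n_selected,
    }
    cols = ["snp", "chr", "pos", "cum_pos", "p", "neglog10_p", "gene_symbol"]
    return df[cols].reset_index(drop=True), meta
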