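"""Shared statistical primitives: rank-sum test, Benjamini-Hochberg
adjustment, Pearson correlation, hypergeometric enrichment.

All tests are two-sided. The rank-sum test uses exact enumeration for
small samples (combined n <= 20, no ties) and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 20  # combined sample size below which the exact test is used


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_hits: int
    study_size: int
    pop_hits: int
    pop_size: int
    p_raw: float
    p_adjusted: float


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue)


def t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Student's t-test p-value (thin delegate)."""
    return float(sps.ttest_ind(np.asarray(x, float), np.asarray(y, float)).pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hypergeom_pvalue(study_hits: int, study_size: int,
                     pop_hits: int, pop_size: int) -> float:
    """Upper-tail hypergeometric P(X >= study_hits)."""
    return float(sps.hypergeom.sf(study_hits - 1, pop_size, pop_hits,
                                  study_size))


def hypergeom_enrichment(
    study: Iterable[str],
    population: Iterable[str],
    term_annotations: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment of a study set within
    a population, BH-adjusted across terms.

    ``term_annotations`` maps term id -> ids annotated with that term.
    Annotations outside the population are ignored.
    """
    study_set = set(study)
    pop_set = set(population)
    if not study_set <= pop_set:
        raise ValueError("study set must be a subset of the population")

    rows = []
    for term_id in sorted(term_annotations):
        hits = set(term_annotations[term_id]) & pop_set
        k = len(hits & study_set)
        p = hypergeom_pvalue(k, len(study_set), len(hits), len(pop_set))
        rows.append((term_id, k, len(hits), p))
    adjusted = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentResult(term_id, k, len(study_set), n_hits, len(pop_set),
                         p, float(padj))
        for (term_id, k, n_hits, p), padj in zip(rows, adjusted)
    ]
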