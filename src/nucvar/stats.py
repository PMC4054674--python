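"""Expression entropy and rank tests for gene-group comparisons.

Expression entropy quantifies the extent of transcriptional
regulation: for a gene with expression x_1..x_n across n conditions,
p_i = x_i / sum(x) and H = -sum p_i log2 p_i (bits, 0*log 0 = 0). A
uniformly expressed (housekeeping-like) gene reaches log2(n) bits; a
gene expressed in a single condition scores 0 — small entropy means
strong, condition-specific regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EntropyResult:
    gene_id: str
    entropy: float  # bits; NaN when invalid
    n_conditions: int
    valid: bool


def expression_entropy(expression, gene_id: str = "") -> EntropyResult:
    """Shannon entropy (base 2) of the normalized expression profile."""
    x = np.asarray(expression, dtype=float)
    if len(x) < 2:
        raise ValueError("need expression in at least 2 conditions")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    total = x.sum()
    if total == 0:
        return EntropyResult(gene_id, float("nan"), len(x), False)
    p = x / total
    nz = p > 0
    h = float(-(p[nz] * np.log2(p[nz])).sum())
    return EntropyResult(gene_id, h, len(x), True)


def wilcoxon_rank_test(sample_a, sample_b, alternative: str = "two_sided",
                       paired: bool = False) -> tuple[float, float]:
    """Rank test between two samples; returns (statistic, p).

    Unpaired (default): Wilcoxon rank-sum / Mann-Whitney U, exact
    enumeration when both samples have n <= 25 and no ties, otherwise
    the tie-corrected normal approximation. Paired: Wilcoxon signed
    rank. ``alternative`` is one of less / greater / two_sided, the
    direction referring to sample_a relative to sample_b.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0  # all pooled values identical
    if paired:
        res = sps.wilcoxon(a, b, alternative=alt)
        return float(res.statistic), float(res.pvalue)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 25 and len(b) <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alt, method=method)
    return float(res.statistic), float(res.pvalue)


def group_comparison_report(values_by_gene: dict[str, float],
                            categories: dict[str, str],
                            paired: bool = False) -> pd.DataFrame:
    """Medians per gene category and one-tail rank tests vs all genes.

    For each non-empty category the report gives n, the median of the
    gene values, the one-tail direction (less/greater, chosen by the
    sign of the median difference from the genome-wide median) and the
    corresponding rank-test p-value against the all-genes distribution.
    """
    all_vals = np.array([v for v in values_by_gene.values() if np.isfinite(v)])
    if len(all_vals) == 0:
        raise ValueError("no finite gene values")
    genome_median = float(np.median(all_vals))
    rows = []
    for cat in sorted(set(categories.values())):
        vals = np.array([values_by_gene[g] for g, c in categories.items()
                         if c == cat and g in values_by_gene
                         and np.isfinite(values_by_gene[g])])
        if len(vals) == 0:
            continue
        med = float(np.median(vals))
        direction = "less" if med < genome_median else "greater"
        _stat, p = wilcoxon_rank_test(vals, all_vals, alternative=direction,
                                      paired=False)
        rows.append({"category": cat, "n": len(vals), "median": med,
                     "direction": direction, "p_value": p,
                     "genome_median": genome_median})
    return pd.DataFrame(rows)
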