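"""Allelic-imbalance testing and ASoC calling.

The central statistic is the exact two-sided binomial test of the null
hypothesis that reads at a heterozygous SNP sample both alleles with equal
probability 0.5.  A SNP whose Benjamini-Hochberg adjusted p-value falls
below the FDR threshold (default 0.05) is called an allele-specific open
chromatin (ASoC) SNP.

The two-sided p-value is the symmetric tail doubling

    p = P(X <= k) + P(X >= n - k),   k = min(ref_count, alt_count),

under X ~ Binomial(n, 0.5), clamped to 1.  Because the Binomial(n, 0.5)
pmf is symmetric this coincides with the "sum of all outcomes at least as
extreme" convention, so the result is independent of any particular
statistics package's tie handling.  Tail sums are exact (no normal
approximation) and never underflow to a reported zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = [
    "binomial_two_sided_p",
    "bh_adjust",
    "call_asoc",
    "reference_bias_qc",
    "cross_celltype_sharing",
    "ReferenceBiasQC",
]

DEFAULT_FDR = 0.05


def binomial_two_sided_p(ref_count, alt_count):
    """Exact two-sided binomial p-value for equal allele sampling.

    Parameters
    ----------
    ref_count, alt_count
        Non-negative read counts (scalars or equal-length arrays).
        Total depth must be >= 1.

    Returns
    -------
    float or ndarray
        p = P(X <= k) + P(X >= n - k) for k = min(ref, alt) under
        Binomial(n, 0.5), clamped to 1.  Symmetric in its arguments.
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    scalar = ref.ndim == 0 and alt.ndim == 0
    ref, alt = np.atleast_1d(ref), np.atleast_1d(alt)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    n = ref + alt
    if np.any(n < 1):
        raise ValueError("total depth must be >= 1 at every SNP")
    k = np.minimum(ref, alt)
    # lower tail P(X <= k) plus upper tail P(X >= n-k) == sf(n-k-1)
    p = binom.cdf(k, n, 0.5) + binom.sf(n - k - 1, n, 0.5)
    p = np.minimum(p, 1.0)
    return float(p[0]) if scalar else p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values, clamped
    to 1, returned in the original order.  Ties receive identical
    q-values.  Empty input yields an empty array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def call_asoc(counts: pd.DataFrame, fdr_threshold: float = DEFAULT_FDR) -> pd.DataFrame:
    """Test every qualified SNP and call ASoC at the given FDR.

    The input is a qualified heterozygous-SNP count table (see
    :mod:`asoc.counts_io`); BH adjustment is computed over exactly this
    set, i.e. over all qualified SNPs of one cell type at a time.  The
    call rule is strict: ``is_asoc`` iff ``q_value < fdr_threshold``.

    Returns the input columns plus ``depth``, ``allelic_ratio``
    (ref_count / depth), ``p_value``, ``q_value`` and ``is_asoc``.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    out = counts.reset_index(drop=True).copy()
    if len(out) == 0:
        for col in ("depth", "allelic_ratio", "p_value", "q_value"):
            out[col] = pd.Series(dtype=float)
        out["is_asoc"] = pd.Series(dtype=bool)
        return out
    ref = out["ref_count"].to_numpy()
    alt = out["alt_count"].to_numpy()
    depth = ref + alt
    if np.any(depth < 1):
        raise ValueError("all SNPs must have depth >= 1; filter upstream")
    out["depth"] = depth
    out["allelic_ratio"] = ref / depth
    out["p_value"] = binomial_two_sided_p(ref, alt)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["is_asoc"] = out["q_value"] < fdr_threshold
    return out


@dataclass
class ReferenceBiasQC:
    """Summary of reference-mapping-bias QC on a result table.

    ``pooled_mean_ratio`` is the unweighted mean reference-allele ratio,
    ``weighted_ratio`` the depth-weighted pooled ratio
    (sum ref / sum depth).  ``biased`` flags a deviation of the pooled
    mean from 0.5 beyond ``margin``; ``volcano`` carries per-SNP
    (allelic_ratio, -log2 p) for plotting.
    """

    n_snps: int
    pooled_mean_ratio: float
    pooled_se: float
    weighted_ratio: float
    margin: float
    biased: bool
    volcano: pd.DataFrame = field(repr=False)


def reference_bias_qc(results: pd.DataFrame, margin: float = 0.02) -> ReferenceBiasQC:
    """Check the result set for global bias toward the reference allele.

    Under unbiased mapping the allelic ratios of mostly-null SNPs center
    on 0.5; a systematic shift indicates residual reference bias.  The
    volcano table (allelic ratio vs -log2 p) is the standard visual for
    this check.
    """
    if len(results) == 0:
        raise ValueError("reference_bias_qc requires at least one result")
    ratio = results["allelic_ratio"].to_numpy(dtype=float)
    mean = float(np.mean(ratio))
    se = float(np.std(ratio, ddof=1) / np.sqrt(len(ratio))) if len(ratio) > 1 else 0.0
    weighted = float(results["ref_count"].sum() / results["depth"].sum())
    volcano = pd.DataFrame(
        {
            "snp_id": results["snp_id"].to_numpy(),
            "allelic_ratio": ratio,
            "neg_log2_p": -np.log2(results["p_value"].to_numpy(dtype=float)),
        }
    )
    return ReferenceBiasQC(
        n_snps=len(results),
        pooled_mean_ratio=mean,
        pooled_se=se,
        weighted_ratio=weighted,
        margin=margin,
        biased=abs(mean - 0.5) > margin,
        volcano=volcano,
    )


def cross_celltype_sharing(
    sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> dict[tuple[str, ...], int]:
    """Count SNPs by exact cell-type membership pattern (Venn counts).

    Given per-cell-type ASoC SNP id sets, returns for every non-empty
    subset of cell types the number of SNPs called in exactly those cell
    types.  The patterns partition the union, so the counts sum to the
    union size.
    """
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    if not items:
        raise ValueError("at least one cell type required")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("cell-type labels must be unique")
    membership: dict[str, set[str]] = {label: set(ids) for label, ids in items}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(membership[c] for c in combo))
            outside = set.union(set(), *(membership[c] for c in labels if c not in combo))
            n = len(inside - outside)
            if n:
                counts[combo] = n
    return counts
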