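"""Expressed-gene calling, tissue-specificity (tau) and age-group comparisons.

The tau index summarises how concentrated a gene's expression is across N
tissues::

    tau = sum_i (1 - x_i) / (N - 1),   x_i = TPM_i / max_i TPM_i

0 means uniform (housekeeping-like) expression, 1 single-tissue expression.
Replicate samples of a tissue are collapsed by the median TPM before tau.
Genes with TPM > 1 in at least one tissue are "expressed"; expressed genes
with tau strictly above 0.85 are tissue-specific and are assigned the tissue
of their maximum.  Age-group comparisons test whether older gene groups have
higher expression (log2 max TPM + 1) and broader expression (number of
tissues with TPM > 1) with a one-sided unpaired Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from genebirth._util import round_half_up
from genebirth.io_formats import ExpressionMatrix, ValidationError
from genebirth.dating import AgedGene

AGE_GROUPS = ("branch 0-1", "branch 2-3", "branch 4-6")


def age_group_of(branch: int, new_gene_branch_threshold: int = 4) -> str:
    """Map a branch index to the coarse three-group age scheme."""
    if branch <= 1:
        return AGE_GROUPS[0]
    if branch < new_gene_branch_threshold:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def call_expressed(tissue_values: Sequence[float], tpm_min: float = 1.0) -> bool:
    """Expressed iff TPM strictly above ``tpm_min`` in at least one tissue."""
    return bool(np.max(tissue_values) > tpm_min)


def tissue_tau(tissue_values: Sequence[float]) -> float:
    """The tau tissue-specificity index of one gene's per-tissue profile."""
    x = np.asarray(tissue_values, dtype=float)
    if x.size < 2:
        raise ValidationError("tau needs at least 2 tissues")
    if (x < 0).any():
        raise ValidationError("negative expression value")
    m = x.max()
    if m <= 0:
        raise ValidationError("tau undefined for an all-zero profile")
    return float((1 - x / m).sum() / (x.size - 1))


def classify_bias(tau: float, tissue_values: Sequence[float],
                  tissues: Sequence[str], tau_min: float = 0.85) -> str | None:
    """Tissue of maximum expression when tau strictly exceeds ``tau_min``.

    Ties at the maximum go to the first tissue in the configured order.
    """
    if tau <= tau_min:
        return None
    x = np.asarray(tissue_values, dtype=float)
    return tissues[int(np.argmax(x))]


@dataclass
class TauResult:
    gene_id: str
    expressed: bool
    tau: float | None
    biased_tissue: str | None
    breadth: int
    max_log2_tpm: float


def profile_genes(expr: ExpressionMatrix, tpm_min: float = 1.0,
                  tau_min: float = 0.85) -> list[TauResult]:
    """Per-gene expressed flag, tau, biased tissue, breadth and peak level."""
    med = expr.tissue_medians()
    out = []
    for gid, row in med.iterrows():
        vals = row.values
        expressed = call_expressed(vals, tpm_min)
        breadth = int((vals > tpm_min).sum())
        max_log = float(np.log2(vals.max() + 1))
        tau = bias = None
        if expressed:
            tau = tissue_tau(vals)
            bias = classify_bias(tau, vals, expr.tissues, tau_min)
        out.append(TauResult(gene_id=str(gid), expressed=expressed, tau=tau,
                             biased_tissue=bias, breadth=breadth,
                             max_log2_tpm=max_log))
    return out


def wilcoxon_one_sided_greater(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided unpaired Wilcoxon rank-sum p-value (alternative: x > y).

    Normal approximation with tie correction; the continuity correction is
    applied toward the null so that identical samples give exactly p = 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        return math.nan
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2  # Mann-Whitney U of x
    mu = n * m / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (nm * (nm - 1))
    var = n * m / 12 * (nm + 1 - tie_term)
    if var <= 0:  # all pooled values identical
        return 0.5
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var)
    return float(stats.norm.sf(z))


@dataclass
class AgeGroupStats:
    """Per-age-group abundance/breadth vectors and pairwise one-sided tests."""

    groups: dict[str, list[str]]                  # group -> gene ids
    max_log2_tpm: dict[str, np.ndarray]
    breadth: dict[str, np.ndarray]
    p_abundance: dict[tuple[str, str], float]     # (older, younger) -> p
    p_breadth: dict[tuple[str, str], float]


def age_group_compare(expr: ExpressionMatrix, aged: Sequence[AgedGene],
                      tpm_min: float = 1.0,
                      new_gene_branch_threshold: int = 4) -> AgeGroupStats:
    """Compare expression abundance and breadth across the three age groups.

    For each ordered pair of groups (older, younger) a one-sided Wilcoxon
    rank-sum test asks whether the older group's values are greater, on
    (a) log2(max tissue TPM + 1) and (b) expression breadth.
    """
    med = expr.tissue_medians()
    groups: dict[str, list[str]] = {g: [] for g in AGE_GROUPS}
    for a in aged:
        if a.branch is None or a.gene_id not in med.index:
            continue
        groups[age_group_of(a.branch, new_gene_branch_threshold)].append(a.gene_id)

    max_log = {}
    breadth = {}
    for g, ids in groups.items():
        block = med.loc[ids]
        max_log[g] = np.log2(block.max(axis=1).values + 1)
        breadth[g] = (block.values > tpm_min).sum(axis=1).astype(float)

    p_ab, p_br = {}, {}
    for i, older in enumerate(AGE_GROUPS):
        for younger in AGE_GROUPS[i + 1:]:
            p_ab[(older, younger)] = wilcoxon_one_sided_greater(max_log[older], max_log[younger])
            p_br[(older, younger)] = wilcoxon_one_sided_greater(breadth[older], breadth[younger])
    return AgeGroupStats(groups=groups, max_log2_tpm=max_log, breadth=breadth,
                         p_abundance=p_ab, p_breadth=p_br)


def bias_breakdown(results: Sequence[TauResult], subset: Sequence[str],
                   tissues: Sequence[str], decimals: int = 2) -> pd.DataFrame:
    """Counts and percentages of tissue-biased genes within a gene subset.

    Percentages are over the subset size (half-up rounding); an ``unbiased``
    row collects expressed subset genes without a biased tissue, so rows sum
    to the number of subset genes with a defined tau.
    """
    subset = [g for g in subset]
    if not subset:
        raise ValidationError("empty subset for bias breakdown")
    by_id = {r.gene_id: r for r in results}
    counts = {t: 0 for t in tissues}
    counts["unbiased"] = 0
    total = 0
    for gid in subset:
        r = by_id.get(gid)
        if r is None or r.tau is None:
            continue
        total += 1
        counts[r.biased_tissue if r.biased_tissue else "unbiased"] += 1
    denom = len(subset)
    rows = [{"tissue": t, "count": c,
             "percent": round_half_up(100.0 * c / denom, decimals)}
            for t, c in counts.items()]
    df = pd.DataFrame(rows).set_index("tissue")
    df.attrs["n_with_tau"] = total
    return df


def tau_results_to_frame(results: Sequence[TauResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "expressed": r.expressed,
        "tau": math.nan if r.tau is None else r.tau,
        "biased_tissue": r.biased_tissue or "",
        "breadth": r.breadth, "max_log2_tpm": r.max_log2_tpm,
    } for r in results]).set_index("gene_id")
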