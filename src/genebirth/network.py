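"""Unsigned weighted co-expression network with module and hub detection.

The workflow mirrors the standard weighted co-expression analysis: soft
thresholding of the absolute Pearson correlation (``a_ij = |r_ij|^beta``,
unsigned, beta = 9 by default), topological-overlap similarity, average
linkage clustering of ``1 - TOM``, a simplified dynamic tree cut (recursive
branch acceptance by size and merge-height gap, with a static-height
fallback), module merging at eigengene dissimilarity 0.5, module eigengenes
(sign-oriented first principal components), module-trait correlations with
one-hot tissue indicators as traits, gene significance (GS), module
membership (kME) and per-module hub calling by maximum kME.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from genebirth.io_formats import ExpressionMatrix, ValidationError


@dataclass
class NetworkConfig:
    soft_power: float = 9.0
    network_type: str = "unsigned"
    min_module_size: int = 30
    merge_threshold: float = 0.5          # eigengene dissimilarity 1 - cor
    cut_method: str = "dynamic_simplified"  # or "static_height"
    static_height_frac: float = 0.99      # fraction of the max merge height
    gap_frac: float = 0.05                # dynamic cut: min relative height gap
    log_transform: bool = True            # analyse log2(TPM + 1)
    seed: int = 0

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValidationError("soft power must be >= 1")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if not (0 < self.merge_threshold < 1):
            raise ValidationError("merge_threshold must lie in (0,1)")
        if self.network_type != "unsigned":
            raise ValidationError("only the unsigned network type is implemented")


def _check_variance(X: pd.DataFrame) -> None:
    sd = X.std(axis=1, ddof=0)
    dead = sd[sd == 0]
    if len(dead):
        raise ValidationError(f"zero-variance gene(s): {list(dead.index[:5])}")


def adjacency(X: pd.DataFrame, beta: float = 9.0) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``|pearson|^beta`` (unit diagonal).

    ``X`` is genes x samples; zero-variance genes must be removed first.
    """
    _check_variance(X)
    r = np.corrcoef(X.values)
    A = np.abs(r) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` where
    ``l_ij = sum_u a_iu a_uj`` over shared neighbours u distinct from i and
    j, and ``k_i`` is the connectivity of i excluding itself.
    """
    A = np.asarray(A, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("adjacency matrix is not symmetric")
    n = A.shape[0]
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    k = B.sum(axis=1)
    L = B @ B  # L[i,j] includes only u != i, j because the diagonal is zeroed
    num = L + B
    den = np.minimum.outer(k, k) + 1.0 - B
    tom = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2, 0.0, 1.0)


def _cluster_tree(tom: np.ndarray):
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    return linkage(squareform(dissim, checks=False), method="average")


def detect_modules(tom: np.ndarray, config: NetworkConfig | None = None) -> np.ndarray:
    """Cluster 1 - TOM and label modules (0 = unassigned).

    Dynamic simplified cut: starting at the root, a branch is split when the
    merge-height gap to its children exceeds ``gap_frac`` of its own height
    and both children hold at least ``min_module_size`` leaves.  Accepted
    clusters must have formed below ``static_height_frac`` of the maximum
    merge height; everything else (including clusters below the minimum
    size) is left unassigned.  Labels are renumbered by decreasing size.
    """
    config = config or NetworkConfig()
    n = tom.shape[0]
    if n < config.min_module_size:
        return np.zeros(n, dtype=int)
    Z = _cluster_tree(tom)
    max_h = Z[:, 2].max()
    cut_h = config.static_height_frac * max_h
    labels = np.zeros(n, dtype=int)

    if config.cut_method == "static_height":
        from scipy.cluster.hierarchy import fcluster

        raw = fcluster(Z, t=cut_h, criterion="distance")
        nxt = 1
        for lab in np.unique(raw):
            idx = np.where(raw == lab)[0]
            if len(idx) >= config.min_module_size:
                labels[idx] = nxt
                nxt += 1
    elif config.cut_method == "dynamic_simplified":
        root = to_tree(Z)
        # static stage: maximal subtrees fully merged below the cut height
        cluster_roots = []

        def descend(node):
            if node.dist <= cut_h:
                cluster_roots.append(node)
            elif not node.is_leaf():
                descend(node.left)
                descend(node.right)

        descend(root)
        # dynamic stage: split a branch when both children are big enough
        # and the merge-height gap is a clear fraction of the branch height
        accepted = []

        def refine(node):
            if node.is_leaf() or node.count < 2 * config.min_module_size:
                accepted.append(node)
                return
            left, right = node.left, node.right
            gap = node.dist - max(left.dist, right.dist)
            if (gap > config.gap_frac * node.dist
                    and min(left.count, right.count) >= config.min_module_size):
                refine(left)
                refine(right)
            else:
                accepted.append(node)

        for node in cluster_roots:
            refine(node)
        nxt = 1
        for node in accepted:
            if node.count >= config.min_module_size:
                labels[node.pre_order(lambda lf: lf.id)] = nxt
                nxt += 1
    else:
        raise ValidationError(f"unknown cut method {config.cut_method!r}")

    return _renumber_by_size(labels)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    mods = [m for m in np.unique(labels) if m != 0]
    mods.sort(key=lambda m: (-(labels == m).sum(), m))
    for new, old in enumerate(mods, start=1):
        out[labels == old] = new
    return out


def module_eigengene(X: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """First principal component of each module, unit variance, sign-oriented.

    Gene rows are z-scored over samples first; the eigengene's sign is
    chosen so that it correlates positively with the module's mean
    standardized profile.  Columns are named ``ME<label>``.
    """
    cols = {}
    for m in sorted(set(labels) - {0}):
        block = X.values[labels == m]
        if block.shape[0] < 2:
            raise ValidationError(f"module {m} has fewer than 2 genes")
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        if (sd == 0).any():
            raise ValidationError(f"zero-variance gene inside module {m}")
        zs = (block - mu) / sd
        _u, s, vt = np.linalg.svd(zs, full_matrices=False)
        if s[0] <= 0:
            raise ValidationError(f"module {m} block has rank 0")
        me = vt[0]
        mean_profile = zs.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        me = me / me.std(ddof=0)
        cols[f"ME{m}"] = me
    return pd.DataFrame(cols, index=X.columns)


def merge_modules(X: pd.DataFrame, labels: np.ndarray,
                  threshold: float = 0.5) -> np.ndarray:
    """Iteratively merge the closest eigengene pair while below the threshold.

    Dissimilarity is ``1 - cor(ME_a, ME_b)``; eigengenes are recomputed
    after every merge, so the procedure terminates (module count strictly
    decreases) and is idempotent at its fixed point.  Labels are renumbered
    by decreasing size at the end.
    """
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        me = module_eigengene(X, labels)
        cor = np.corrcoef(me.values.T)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        d = 1.0 - cor[i, j]
        if d >= threshold:
            break
        a, b = mods[i], mods[j]
        labels[labels == b] = a
    return _renumber_by_size(labels)


def one_hot_traits(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample tissue indicator matrix (samples x tissues)."""
    data = {t: [1.0 if expr.sample_tissue[s] == t else 0.0 for s in expr.samples]
            for t in expr.tissues}
    return pd.DataFrame(data, index=expr.samples)[list(expr.tissues)]


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and Student-t (n-2 df) p-values per (module, trait).

    Constant traits yield NaN in both matrices (flagged, not raised).
    """
    R = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    P = R.copy()
    for mcol in eigengenes.columns:
        for tcol in traits.columns:
            tv = traits[tcol].values
            if np.std(tv) == 0:
                R.loc[mcol, tcol] = math.nan
                P.loc[mcol, tcol] = math.nan
                continue
            r, p = stats.pearsonr(eigengenes[mcol].values, tv)
            R.loc[mcol, tcol] = r
            P.loc[mcol, tcol] = p
    return R, P


def gene_significance(X: pd.DataFrame, trait: Sequence[float]) -> pd.Series:
    """GS = |pearson(gene, trait)| per gene; constant genes flagged as NaN."""
    t = np.asarray(trait, dtype=float)
    if np.std(t) == 0:
        raise ValidationError("constant trait")
    vals = []
    for _, row in X.iterrows():
        x = row.values
        vals.append(math.nan if np.std(x) == 0 else abs(stats.pearsonr(x, t)[0]))
    return pd.Series(vals, index=X.index)


def kme_and_hubs(X: pd.DataFrame, eigengenes: pd.DataFrame, labels: np.ndarray,
                 candidate_set: Sequence[str] | None = None
                 ) -> tuple[pd.DataFrame, dict[int, str]]:
    """Module membership (kME) per gene per module and the hub of each module.

    ``kME_gm = pearson(x_g, ME_m)``.  The hub of module m is the gene inside
    module m (restricted to ``candidate_set`` when given) with the largest
    kME; ties break to the lexicographically smallest gene id.  A module
    whose candidate intersection is empty reports no hub.
    """
    genes = list(X.index)
    kme = pd.DataFrame(index=genes, columns=eigengenes.columns, dtype=float)
    for mcol in eigengenes.columns:
        me = eigengenes[mcol].values
        for g, row in zip(genes, X.values):
            kme.loc[g, mcol] = (math.nan if np.std(row) == 0
                                else stats.pearsonr(row, me)[0])
    allowed = set(candidate_set) if candidate_set is not None else None
    hubs: dict[int, str] = {}
    for m in sorted(set(labels) - {0}):
        members = [g for g, lab in zip(genes, labels) if lab == m]
        if allowed is not None:
            members = [g for g in members if g in allowed]
        if not members:
            continue
        col = f"ME{m}"
        hubs[int(m)] = min(members, key=lambda g: (-kme.loc[g, col], g))
    return kme, hubs


@dataclass
class CoexpressionResult:
    labels: pd.Series                      # gene -> module label (0 unassigned)
    eigengenes: pd.DataFrame               # samples x MEs
    module_trait_r: pd.DataFrame
    module_trait_p: pd.DataFrame
    kme: pd.DataFrame                      # genes x MEs
    gs: pd.DataFrame                       # genes x traits
    hubs: dict[int, str]

    @property
    def module_sizes(self) -> dict[int, int]:
        vc = self.labels.value_counts()
        return {int(m): int(c) for m, c in vc.items() if m != 0}


def run_network(expr: ExpressionMatrix, config: NetworkConfig | None = None,
                candidate_set: Sequence[str] | None = None,
                tpm_min: float = 1.0) -> CoexpressionResult:
    """End-to-end network construction on the expressed-gene universe.

    Genes with TPM strictly above ``tpm_min`` in at least one sample and
    nonzero variance enter the network; analysis runs on log2(TPM + 1) when
    configured (the default).
    """
    config = config or NetworkConfig()
    V = expr.values
    keep = (V.values > tpm_min).any(axis=1)
    X = V.loc[keep]
    X = np.log2(X + 1) if config.log_transform else X.copy()
    X = X[X.std(axis=1, ddof=0) > 0]
    if X.shape[0] == 0:
        raise ValidationError("no expressed, variable genes for the network")

    A = adjacency(X, config.soft_power)
    tom = tom_similarity(A)
    labels = detect_modules(tom, config)
    if (labels > 0).any():
        labels = merge_modules(X, labels, config.merge_threshold)
        eig = module_eigengene(X, labels)
    else:
        eig = pd.DataFrame(index=X.columns)

    traits = one_hot_traits(expr).loc[X.columns]
    if eig.shape[1]:
        R, P = module_trait_correlation(eig, traits)
        kme, hubs = kme_and_hubs(X, eig, labels, candidate_set)
    else:
        R = pd.DataFrame(columns=traits.columns, dtype=float)
        P = R.copy()
        kme = pd.DataFrame(index=X.index, dtype=float)
        hubs = {}
    gs = pd.DataFrame({t: gene_significance(X, traits[t].values) for t in traits.columns})

    return CoexpressionResult(
        labels=pd.Series(labels, index=X.index, name="module"),
        eigengenes=eig, module_trait_r=R, module_trait_p=P,
        kme=kme, gs=gs, hubs=hubs,
    )
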