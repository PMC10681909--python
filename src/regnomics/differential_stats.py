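"""QC filtering, normalization, marker detection and composition testing.

Defaults encode the quality cutoffs used throughout the pipeline: UMI in
[500, 25000], mitochondrial fraction <= 0.005, doublet score <= 0.0025 for
cells; FRiP >= 0.15 and fragment counts in [30000, 1500000] for ATAC nuclei.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .errors import ConfigError, InputError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCParams:
    min_umi: int = 500
    max_umi: int = 25_000
    max_mito_fraction: float = 0.005
    max_doublet_score: float = 0.0025
    atac_min_frip: float = 0.15
    atac_min_fragments: int = 30_000
    atac_max_fragments: int = 1_500_000

    def __post_init__(self) -> None:
        if self.min_umi >= self.max_umi:
            raise ConfigError("min_umi must be < max_umi")
        if self.atac_min_fragments >= self.atac_max_fragments:
            raise ConfigError("atac_min_fragments must be < atac_max_fragments")
        for name in ("max_mito_fraction", "max_doublet_score", "atac_min_frip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class NormalizedMatrix:
    """ln(1 + count * scale / umi_total) values, sparse, genes x cells."""

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    metadata: pd.DataFrame
    scale: float

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_means(self) -> np.ndarray:
        return np.asarray(self.values.mean(axis=1)).ravel()


def qc_filter_cells(
    matrix: ExpressionMatrix, params: QCParams | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Remove cells failing any QC rule.

    The report attributes each removed cell to its first failing rule in the
    fixed order min_umi, max_umi, mito, doublet.
    """
    params = params or QCParams()
    meta = matrix.metadata
    for col in ("mito_fraction", "doublet_score"):
        if col not in meta.columns:
            raise InputError(f"metadata missing required column {col!r}")
    umi = meta["umi_total"].to_numpy()
    mito = meta["mito_fraction"].to_numpy()
    doub = meta["doublet_score"].to_numpy()

    fail_min = umi < params.min_umi
    fail_max = ~fail_min & (umi > params.max_umi)
    fail_mito = ~fail_min & ~fail_max & (mito > params.max_mito_fraction)
    fail_doub = (
        ~fail_min & ~fail_max & ~fail_mito & (doub > params.max_doublet_score)
    )
    keep = ~(fail_min | fail_max | fail_mito | fail_doub)
    report = {
        "n_input": int(len(keep)),
        "n_retained": int(keep.sum()),
        "removed": {
            "min_umi": int(fail_min.sum()),
            "max_umi": int(fail_max.sum()),
            "mito": int(fail_mito.sum()),
            "doublet": int(fail_doub.sum()),
        },
    }
    return matrix.subset_cells(keep), report


def qc_filter_nuclei(
    table: pd.DataFrame, params: QCParams | None = None
) -> tuple[pd.DataFrame, dict]:
    """Filter a per-nucleus ATAC QC table with columns frip, fragments."""
    params = params or QCParams()
    for col in ("frip", "fragments"):
        if col not in table.columns:
            raise InputError(f"nucleus table missing required column {col!r}")
    frip = table["frip"].to_numpy()
    frags = table["fragments"].to_numpy()
    fail_frip = frip < params.atac_min_frip
    fail_min = ~fail_frip & (frags < params.atac_min_fragments)
    fail_max = ~fail_frip & ~fail_min & (frags > params.atac_max_fragments)
    keep = ~(fail_frip | fail_min | fail_max)
    report = {
        "n_input": int(len(table)),
        "n_retained": int(keep.sum()),
        "removed": {
            "frip": int(fail_frip.sum()),
            "min_fragments": int(fail_min.sum()),
            "max_fragments": int(fail_max.sum()),
        },
    }
    return table.loc[keep].copy(), report


def normalize_log(matrix: ExpressionMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize to `scale` counts per cell, then ln(1 + x)."""
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = [matrix.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise InputError(f"cells with zero total counts: {bad}")
    csc = sp.csc_matrix(matrix.counts, dtype=float)
    inv = scale / totals
    csc.data *= np.repeat(inv, np.diff(csc.indptr))
    np.log1p(csc.data, out=csc.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(csc),
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        metadata=matrix.metadata.copy(),
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum marker detection
# ---------------------------------------------------------------------------

def _ranksum_pvalues(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum, normal approximation with tie
    correction and continuity correction. x1, x2: genes x cells arrays."""
    n1, n2 = x1.shape[1], x2.shape[1]
    n = n1 + n2
    combined = np.concatenate([x1, x2], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    srt = np.sort(combined, axis=1)
    new_run = np.ones_like(srt, dtype=bool)
    new_run[:, 1:] = srt[:, 1:] != srt[:, :-1]
    tie_term = np.empty(combined.shape[0])
    for g in range(combined.shape[0]):
        run_lengths = np.diff(np.append(np.flatnonzero(new_run[g]), n))
        tie_term[g] = (run_lengths.astype(float) ** 3 - run_lengths).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = np.zeros_like(u1)
    pos = var > 0
    num = np.abs(u1 - mu) - 0.5
    np.clip(num, 0, None, out=num)
    z[pos] = num[pos] / np.sqrt(var[pos])
    return 2.0 * stats.norm.sf(z)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adj, 0, 1, out=adj)
    out = np.empty(m)
    out[order] = adj
    return out


def find_markers(
    norm: NormalizedMatrix,
    group1: np.ndarray,
    group2: np.ndarray,
    min_pct: float = 0.01,
    logfc_threshold: float = 0.25,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum marker test between two cell groups.

    group1/group2 are cell index arrays or boolean masks over norm's cells.
    Genes below the expression or fold-change prefilter carry p = 1 and
    tested = False; BH adjustment runs over tested genes only.
    """
    idx1 = _as_index(group1, norm.n_cells)
    idx2 = _as_index(group2, norm.n_cells)
    if len(idx1) == 0 or len(idx2) == 0:
        raise InputError("both groups must be non-empty")
    if len(idx1) < 3 or len(idx2) < 3:
        raise InputError("each group needs >= 3 cells")
    if np.intersect1d(idx1, idx2).size:
        raise InputError("groups overlap")

    x1 = np.asarray(norm.values[:, idx1].todense())
    x2 = np.asarray(norm.values[:, idx2].todense())
    pct1 = (x1 > 0).mean(axis=1)
    pct2 = (x2 > 0).mean(axis=1)
    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    log2fc = np.log2((mean1 + 1.0) / (mean2 + 1.0))

    tested = ((pct1 >= min_pct) | (pct2 >= min_pct)) & (
        np.abs(log2fc) >= logfc_threshold
    )
    pvals = np.ones(norm.n_genes)
    if tested.any():
        pvals[tested] = _ranksum_pvalues(x1[tested], x2[tested])
    adj = np.full(norm.n_genes, np.nan)
    if tested.any():
        adj[tested] = bh_adjust(pvals[tested])
    return pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "log2_fold_change": log2fc,
            "pct_group1": pct1,
            "pct_group2": pct2,
            "p_value": pvals,
            "adjusted_p": adj,
            "tested": tested,
        }
    )


def _as_index(group, n: int) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype == bool:
        if arr.size != n:
            raise InputError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# Cluster composition permutation test
# ---------------------------------------------------------------------------

def composition_test(
    meta: pd.DataFrame,
    cluster_col: str = "cluster",
    condition_col: str = "condition",
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-cluster log2 fold difference of proportions between two conditions
    with a label-permutation two-sided p-value.

    log2_fold_difference = log2((prop1 + eps) / (prop2 + eps)) with
    eps = 1 / total cells. p = (1 + #{|perm| >= |obs|}) / (1 + n_perm).
    """
    for col in (cluster_col, condition_col):
        if col not in meta.columns:
            raise InputError(f"metadata missing column {col!r}")
        if meta[col].isna().any():
            raise InputError(f"unlabeled cells in column {col!r}")
    conditions = sorted(meta[condition_col].unique())
    if len(conditions) != 2:
        raise InputError(f"need exactly 2 conditions, got {conditions}")
    clusters = sorted(meta[cluster_col].unique())
    k = len(clusters)
    ccode = meta[cluster_col].map({c: i for i, c in enumerate(clusters)}).to_numpy()
    in_c1 = (meta[condition_col] == conditions[0]).to_numpy()
    n_total = len(meta)
    n1 = int(in_c1.sum())
    n2 = n_total - n1
    eps = 1.0 / n_total

    def _stat(mask1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        cnt1 = np.bincount(ccode[mask1], minlength=k)
        cnt2 = np.bincount(ccode[~mask1], minlength=k)
        p1 = cnt1 / n1
        p2 = cnt2 / n2
        return np.log2((p1 + eps) / (p2 + eps)), p1, p2

    obs, prop1, prop2 = _stat(in_c1)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(k, dtype=int)
    labels = in_c1.copy()
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        perm_stat, _, _ = _stat(perm)
        exceed += np.abs(perm_stat) >= np.abs(obs) - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    present_both = (prop1 > 0) | (prop2 > 0)
    for i, c in enumerate(clusters):
        if not present_both[i]:
            logger.warning("cluster %s absent in both conditions; skipped", c)
    return pd.DataFrame(
        {
            "cluster": clusters,
            "proportion_condition1": prop1,
            "proportion_condition2": prop2,
            "log2_fold_difference": obs,
            "permutation_p": pvals,
            "n_permutations": n_perm,
        }
    ).loc[present_both.nonzero()[0]].reset_index(drop=True)
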