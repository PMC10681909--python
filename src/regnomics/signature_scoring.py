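"""Gene-set module scoring against expression-matched background genes.

The raw per-cell score is the mean normalized expression of the set genes
minus the mean over a background pool drawn from the same equal-frequency
expression bins, with pool_factor background genes per set gene (so the pool
is exactly pool_factor times the set size, duplicates allowed across genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InputError
from .differential_stats import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InputError(f"gene set {self.name!r} has duplicate ids")


@dataclass
class ScoreVector:
    cell_ids: list[str]
    raw: np.ndarray
    z: np.ndarray | None
    provenance: dict

    def __len__(self) -> int:
        return len(self.cell_ids)


def _expression_bins(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene by mean expression (stable ties)."""
    order = np.argsort(gene_means, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    return (ranks * n_bins) // len(gene_means)


def module_score(
    norm: NormalizedMatrix,
    genes: GeneSet,
    n_bins: int = 24,
    pool_factor: int = 10,
    seed: int | None = 0,
) -> ScoreVector:
    """Score a gene set per cell against bin-matched random background genes.

    For each set gene, pool_factor background genes are sampled uniformly
    without replacement from the gene's expression bin (set genes excluded
    from candidacy); bins smaller than pool_factor fall back to sampling
    with replacement, with a warning.
    """
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    present = [g for g in genes.genes if g in gene_index]
    missing = [g for g in genes.genes if g not in gene_index]
    if not present:
        raise InputError(
            f"gene set {genes.name!r} has no genes in the matrix"
        )
    if missing:
        logger.warning(
            "gene set %s: %d/%d genes missing from matrix",
            genes.name,
            len(missing),
            len(genes.genes),
        )
    if len(present) < 0.5 * len(genes.genes):
        raise InputError(
            f"gene set {genes.name!r}: fewer than 50% of genes present"
        )

    means = norm.gene_means()
    bins = _expression_bins(means, n_bins)
    set_idx = np.array([gene_index[g] for g in present])
    in_set = np.zeros(norm.n_genes, dtype=bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    background_idx: list[int] = []
    for gi in set_idx:
        candidates = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if candidates.size == 0:
            raise InputError(
                f"no background candidates in bin of gene {norm.gene_ids[gi]}"
            )
        if candidates.size < pool_factor:
            logger.warning(
                "bin of gene %s has %d candidates < pool_factor %d; "
                "sampling with replacement",
                norm.gene_ids[gi],
                candidates.size,
                pool_factor,
            )
            picks = rng.choice(candidates, size=pool_factor, replace=True)
        else:
            picks = rng.choice(candidates, size=pool_factor, replace=False)
        background_idx.extend(int(p) for p in picks)

    bg_idx = np.asarray(background_idx)
    set_expr = np.asarray(norm.values[set_idx].todense())
    bg_expr = np.asarray(norm.values[bg_idx].todense())
    raw = set_expr.mean(axis=0) - bg_expr.mean(axis=0)
    provenance = {
        "gene_set": genes.name,
        "set_genes_used": present,
        "missing_genes": missing,
        "n_bins": n_bins,
        "pool_factor": pool_factor,
        "seed": seed,
        "background_gene_ids": [norm.gene_ids[i] for i in bg_idx],
        "rng": "numpy.random.default_rng (PCG64)",
    }
    return ScoreVector(
        cell_ids=list(norm.cell_ids), raw=raw, z=None, provenance=provenance
    )


def zscore(scores: ScoreVector) -> ScoreVector:
    """Population z-transform of raw scores; all-zero if SD is 0."""
    raw = scores.raw
    if raw.size < 2:
        raise InputError("need >= 2 cells to z-score")
    sd = raw.std()
    if sd == 0:
        logger.warning("raw scores constant; z-scores set to 0")
        z = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sd
    return ScoreVector(
        cell_ids=scores.cell_ids, raw=raw, z=z, provenance=scores.provenance
    )


def compare_scores(
    scores: ScoreVector,
    group1: np.ndarray,
    group2: np.ndarray,
    paired: bool = False,
) -> tuple[float, float]:
    """Test score difference between two disjoint cell groups.

    Unpaired: two-sided Wilcoxon rank-sum (Mann-Whitney U). Paired:
    Wilcoxon signed-rank on matched pairs (requires equal group sizes).
    Returns (statistic, p_value).
    """
    idx1 = _as_index(group1, len(scores))
    idx2 = _as_index(group2, len(scores))
    if np.intersect1d(idx1, idx2).size:
        raise InputError("groups overlap")
    x1 = scores.raw[idx1]
    x2 = scores.raw[idx2]
    if paired:
        if len(x1) != len(x2):
            raise InputError("paired mode requires equal group sizes")
        res = stats.wilcoxon(x1, x2)
    else:
        if len(x1) < 3 or len(x2) < 3:
            raise InputError("unpaired mode requires >= 3 cells per group")
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _as_index(group, n: int) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype == bool:
        if arr.size != n:
            raise InputError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    return arr.astype(int)
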