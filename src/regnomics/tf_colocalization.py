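"""TF-family motif co-occurrence networks and spectral community detection.

Families' per-peak motif counts are correlated (Pearson) across a peak
subset; the resulting weighted graph is partitioned with Newman's
leading-eigenvector modularity method. Negative/floored edges are removed
before modularity analysis (weight_floor, default 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from .errors import InputError
from .io_formats import FamilyMap
from .motif_scan import MotifHitMatrix

logger = logging.getLogger(__name__)


@dataclass
class FamilyCountMatrix:
    counts: pd.DataFrame  # index peak_id, columns family labels


@dataclass
class FamilyNetwork:
    families: list[str]
    weights: np.ndarray  # symmetric Pearson r matrix, diag = 1 (excluded from edges)
    dropped: list[str]

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.families)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "family_a": self.families[i],
                        "family_b": self.families[j],
                        "r": self.weights[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class Partition:
    membership: dict[str, int]
    modularity: float

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        return out


def aggregate_families(hits: MotifHitMatrix, fam: FamilyMap) -> FamilyCountMatrix:
    """Sum per-peak motif hit counts over each family's member motifs."""
    unmapped = [m for m in hits.motif_ids if m not in fam.mapping]
    if unmapped:
        raise InputError(f"motifs without family annotation: {unmapped}")
    fam_of = np.asarray([fam.mapping[m] for m in hits.motif_ids])
    agg = hits.counts.T.groupby(fam_of).sum().T
    agg.index.name = "peak_id"
    return FamilyCountMatrix(counts=agg)


def correlation_network(
    counts: FamilyCountMatrix,
    peak_subset: list[str] | None = None,
    min_nonzero: int = 5,
) -> FamilyNetwork:
    """Pearson correlation between every family pair over a peak subset.

    Families with fewer than min_nonzero nonzero counts, or zero variance,
    are dropped with a warning.
    """
    mat = counts.counts
    if peak_subset is not None:
        keep = [p for p in peak_subset if p in mat.index]
        if not keep:
            raise InputError("peak subset does not intersect the count matrix")
        mat = mat.loc[keep]
    if len(mat) < 3:
        raise InputError("need >= 3 peaks to correlate")

    x = mat.to_numpy(dtype=float)
    nonzero = (x > 0).sum(axis=0)
    variance = x.var(axis=0)
    ok = (nonzero >= min_nonzero) & (variance > 0)
    dropped = [f for f, good in zip(mat.columns, ok) if not good]
    for f in dropped:
        logger.warning("family %s dropped (low support or zero variance)", f)
    families = [f for f, good in zip(mat.columns, ok) if good]
    if not families:
        return FamilyNetwork(families=[], weights=np.zeros((0, 0)), dropped=dropped)
    r = np.corrcoef(x[:, ok], rowvar=False)
    r = np.atleast_2d(r)
    return FamilyNetwork(families=families, weights=r, dropped=dropped)


# ---------------------------------------------------------------------------
# Newman leading-eigenvector community detection
# ---------------------------------------------------------------------------

def _leading_eigen_split(bg: np.ndarray, m2: float, tol: float = 1e-10):
    """One bisection step on a group's generalized modularity matrix.

    Returns a boolean split array or None if the group is indivisible.
    """
    bmod = bg - np.diag(bg.sum(axis=1))
    evals, evecs = np.linalg.eigh(bmod)
    lead = evecs[:, -1]
    if evals[-1] <= tol:
        return None
    # deterministic sign: largest-magnitude entry positive
    k = int(np.argmax(np.abs(lead)))
    if lead[k] < 0:
        lead = -lead
    s = np.where(lead >= 0, 1.0, -1.0)
    if np.all(s > 0) or np.all(s < 0):
        return None
    dq = float(s @ bmod @ s) / (2.0 * m2)
    if dq <= tol:
        return None
    return s > 0


def spectral_communities(net: FamilyNetwork, weight_floor: float = 0.0) -> Partition:
    """Partition the family network by leading-eigenvector modularity.

    Edges with weight <= weight_floor are removed first. Connected
    components are split recursively while a split increases modularity;
    isolated nodes become singleton communities.
    """
    n = len(net.families)
    if n < 2:
        return Partition(
            membership={f: i for i, f in enumerate(net.families)}, modularity=0.0
        )
    a = net.weights.copy()
    np.fill_diagonal(a, 0.0)
    a[a <= weight_floor] = 0.0

    m2 = a.sum()  # 2m
    if m2 <= 0:
        logger.warning("graph empty after weight filtering; all singletons")
        return Partition(
            membership={f: i for i, f in enumerate(net.families)}, modularity=0.0
        )

    deg = a.sum(axis=1)
    b = a - np.outer(deg, deg) / m2

    n_comp, comp_labels = connected_components(csr_matrix(a), directed=False)
    membership = np.zeros(n, dtype=int)
    next_id = 0
    for c in range(n_comp):
        nodes = np.flatnonzero(comp_labels == c)
        stack = [nodes]
        while stack:
            group = stack.pop()
            if len(group) < 2:
                membership[group] = next_id
                next_id += 1
                continue
            split = _leading_eigen_split(b[np.ix_(group, group)], m2)
            if split is None:
                membership[group] = next_id
                next_id += 1
            else:
                stack.append(group[split])
                stack.append(group[~split])

    q = 0.0
    for cid in np.unique(membership):
        nodes = np.flatnonzero(membership == cid)
        q += b[np.ix_(nodes, nodes)].sum()
    q /= m2
    return Partition(
        membership={f: int(membership[i]) for i, f in enumerate(net.families)},
        modularity=float(q),
    )


def compare_partitions(
    p1: Partition,
    p2: Partition,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Co-membership flags for designated node pairs plus the adjusted Rand
    index between two partitions over the same node set."""
    nodes1 = set(p1.membership)
    nodes2 = set(p2.membership)
    if nodes1 != nodes2:
        raise InputError("partitions cover different node sets")
    nodes = sorted(nodes1)
    labels1 = [p1.membership[x] for x in nodes]
    labels2 = [p2.membership[x] for x in nodes]
    ari = float(adjusted_rand_score(labels1, labels2))
    rows = []
    for a, bnode in pairs or []:
        if a not in nodes1 or bnode not in nodes1:
            raise InputError(f"pair ({a}, {bnode}) not in node set")
        rows.append(
            {
                "family_a": a,
                "family_b": bnode,
                "together_p1": p1.membership[a] == p1.membership[bnode],
                "together_p2": p2.membership[a] == p2.membership[bnode],
            }
        )
    return pd.DataFrame(rows), ari
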