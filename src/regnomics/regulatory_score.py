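"""Peak-to-gene assignment and the normalized motif score (NMS).

A peak is assigned to every gene whose body or strand-aware promoter
(promoter_bp upstream of the TSS, clipped at 0) it overlaps under half-open
interval intersection. NMS(gene, TF) = sum over assigned peaks of
accessibility * motif_count / peak_length_kb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io_formats import FamilyMap, GeneAnnotation, PeakSet
from .motif_scan import MotifHitMatrix


@dataclass
class PeakGeneAssignment:
    gene_to_peaks: dict[str, list[str]]
    promoter_bp: int

    def peaks_for(self, gene_id: str) -> list[str]:
        return self.gene_to_peaks.get(gene_id, [])


def extended_interval(
    start: int, end: int, strand: str, promoter_bp: int
) -> tuple[int, int]:
    """Gene body plus the promoter_bp upstream of the TSS, clipped at 0."""
    if strand == "+":
        return max(0, start - promoter_bp), end
    return start, end + promoter_bp


def assign_peaks(
    peaks: PeakSet, genes: GeneAnnotation, promoter_bp: int = 2000
) -> PeakGeneAssignment:
    """Assign every peak to all genes whose body+promoter it overlaps."""
    pf = peaks.frame
    gf = genes.frame
    mapping: dict[str, list[str]] = {g: [] for g in gf["gene_id"]}
    for chrom, gsub in gf.groupby("chrom", sort=False):
        psub = pf[pf["chrom"] == chrom]
        if psub.empty:
            continue
        pstart = psub["start"].to_numpy()
        pend = psub["end"].to_numpy()
        pids = psub["peak_id"].to_numpy()
        ext = np.array(
            [
                extended_interval(s, e, st, promoter_bp)
                for s, e, st in zip(gsub["start"], gsub["end"], gsub["strand"])
            ]
        )
        # half-open overlap: peak.start < ext_end and peak.end > ext_start
        overlap = (pstart[None, :] < ext[:, 1][:, None]) & (
            pend[None, :] > ext[:, 0][:, None]
        )
        for gi, gid in enumerate(gsub["gene_id"]):
            mapping[gid] = [str(p) for p in pids[overlap[gi]]]
    return PeakGeneAssignment(gene_to_peaks=mapping, promoter_bp=promoter_bp)


@dataclass
class NMSTable:
    values: pd.DataFrame  # index gene_id, columns tf/family labels
    population: str
    level: str  # "tf" or "family"


def compute_nms(
    hits: MotifHitMatrix,
    peaks: PeakSet,
    assignment: PeakGeneAssignment,
    population: str,
    level: str = "tf",
    family_map: FamilyMap | None = None,
) -> NMSTable:
    """NMS(g, T) = sum over assigned peaks i of a_i * m_i(T) / L_i.

    a_i is the peak's mean accessibility in `population`, m_i(T) the motif
    hit count (summed over a family's member motifs when level="family"),
    L_i the peak length in kilobases.
    """
    if peaks.accessibility is None or population not in peaks.accessibility.columns:
        have = [] if peaks.accessibility is None else list(peaks.accessibility.columns)
        raise InputError(f"population {population!r} not in accessibility {have}")
    if level not in ("tf", "family"):
        raise InputError(f"level must be 'tf' or 'family', got {level!r}")

    count_mat = hits.counts
    if level == "family" and family_map is None:
        raise InputError("family_map required for level='family'")

    acc = peaks.accessibility[population].reindex(count_mat.index).to_numpy()
    length_kb = (
        peaks.frame.set_index("peak_id")
        .loc[count_mat.index]
        .pipe(lambda d: (d["end"] - d["start"]).to_numpy() / 1000.0)
    )
    weights = acc / length_kb
    weighted = count_mat.to_numpy() * weights[:, None]

    peak_pos = {p: i for i, p in enumerate(count_mat.index)}
    gene_ids = list(assignment.gene_to_peaks)
    out = np.zeros((len(gene_ids), weighted.shape[1]))
    for gi, gid in enumerate(gene_ids):
        rows = [peak_pos[p] for p in assignment.peaks_for(gid) if p in peak_pos]
        if rows:
            out[gi] = weighted[rows].sum(axis=0)
    values = pd.DataFrame(
        out, index=pd.Index(gene_ids, name="gene_id"), columns=count_mat.columns
    )
    if level == "family":
        # summed after weighting so family NMS is exactly the sum of its
        # member-TF NMS values
        fam_of = np.asarray([family_map[m] for m in values.columns])
        values = values.T.groupby(fam_of).sum().T
        values.index.name = "gene_id"
    return NMSTable(values=values, population=population, level=level)


def compare_nms(
    table: NMSTable,
    deg_genes: list[str],
    background_genes: list[str],
    tf_or_family: str,
    method: str = "mannwhitney",
) -> tuple[float, float, float]:
    """Compare NMS values of a DEG set against background genes.

    Returns (statistic, p_value, median difference deg - background) from a
    two-sided Mann-Whitney U test (or Kolmogorov-Smirnov with method="ks").
    """
    if tf_or_family not in table.values.columns:
        raise InputError(f"{tf_or_family!r} not in NMS table columns")
    col = table.values[tf_or_family]
    deg = [g for g in deg_genes if g in col.index]
    bgd = [g for g in background_genes if g in col.index and g not in set(deg)]
    if len(deg) < 5 or len(bgd) < 5:
        raise InputError(
            f"need >= 5 genes per set after intersection, got "
            f"{len(deg)} and {len(bgd)}"
        )
    x = col.loc[deg].to_numpy()
    y = col.loc[bgd].to_numpy()
    if method == "ks":
        res = stats.ks_2samp(x, y)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise InputError(f"unknown method {method!r}")
    effect = float(np.median(x) - np.median(y))
    return float(res.statistic), float(res.pvalue), effect
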