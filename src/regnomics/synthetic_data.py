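"""Simulators for every pipeline input, with planted ground truth.

Two generators: `simulate_expression` produces a negative-binomial
gene x cell count matrix with one module-high cluster, condition-specific
fold changes, composition shifts and QC covariates; `simulate_regulatory`
produces a genome, gene annotation, peaks, PWMs with family annotations,
planted motif occurrences (denser near designated target genes, co-planted
in family blocks) and per-population peak accessibility.

All randomness flows from one integer seed through fixed per-stage
substreams of numpy's PCG64 generator, so outputs are bit-identical across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from . import io_formats
from .io_formats import (
    ExpressionMatrix,
    FamilyMap,
    GeneAnnotation,
    GenomeSequences,
    Motif,
    PeakSet,
    PWMCollection,
)

_BASES = np.array(list("ACGT"))

# substream indices; rng = default_rng([seed, _STREAM[name]])
_STREAM = {
    "expression": 0,
    "qc_covariates": 1,
    "genome": 2,
    "planting": 3,
    "accessibility": 4,
}


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_cells: int = 500
    n_clusters: int = 4
    isg_panel_size: int = 96
    isg_shift: float = 0.0
    n_deg: int = 0
    deg_fold: float = 1.0
    dispersion: float = 0.5
    depth_mean: float = 2500.0
    cluster_proportions_by_condition: dict[str, list[float]] | None = None
    qc_fail_fraction: float = 0.05
    genome_n_seqs: int = 12
    seq_len: int = 20_000
    n_motifs: int = 8
    motif_len: int = 8
    n_families: int = 4
    target_density_multiplier: float = 3.0
    target_fraction: float = 0.25
    base_plant_rate: float = 0.25
    co_plant_prob: float = 0.9
    target_accessibility_boost: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_cells",
            "n_clusters",
            "isg_panel_size",
            "dispersion",
            "depth_mean",
            "genome_n_seqs",
            "seq_len",
            "n_motifs",
            "motif_len",
            "n_families",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_deg < 0:
            raise ConfigError("n_deg must be >= 0")
        if self.isg_panel_size > self.n_genes:
            raise ConfigError("isg_panel_size exceeds n_genes")
        if self.isg_panel_size + self.n_deg > self.n_genes:
            raise ConfigError("n_deg plus isg_panel_size exceeds n_genes")
        if self.motif_len > self.seq_len:
            raise ConfigError("motif_len exceeds seq_len")
        if self.n_families > self.n_motifs:
            raise ConfigError("n_families exceeds n_motifs")
        if not 0.0 <= self.qc_fail_fraction < 1.0:
            raise ConfigError("qc_fail_fraction must be in [0, 1)")
        if self.cluster_proportions_by_condition is None:
            even = [1.0 / self.n_clusters] * self.n_clusters
            self.cluster_proportions_by_condition = {"cond1": even, "cond2": even}
        props = self.cluster_proportions_by_condition
        if len(props) != 2:
            raise ConfigError(
                "cluster_proportions_by_condition needs exactly 2 conditions"
            )
        for cond, p in props.items():
            if len(p) != self.n_clusters:
                raise ConfigError(
                    f"cluster_proportions_by_condition[{cond!r}] has "
                    f"{len(p)} entries, expected n_clusters={self.n_clusters}"
                )
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ConfigError(
                    f"cluster_proportions_by_condition[{cond!r}] is not a "
                    "probability vector"
                )

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stage]])


@dataclass
class GroundTruth:
    isg_gene_ids: list[str] = field(default_factory=list)
    isg_high_cluster: str | None = None
    deg_gene_ids: list[str] = field(default_factory=list)
    enriched_clusters: list[str] = field(default_factory=list)
    target_gene_ids: list[str] = field(default_factory=list)
    planted_hit_counts: pd.DataFrame | None = None
    family_blocks: dict[str, int] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "isg_gene_ids": self.isg_gene_ids,
            "isg_high_cluster": self.isg_high_cluster,
            "deg_gene_ids": self.deg_gene_ids,
            "enriched_clusters": self.enriched_clusters,
            "target_gene_ids": self.target_gene_ids,
            "family_blocks": self.family_blocks,
            "extras": self.extras,
        }
        if self.planted_hit_counts is not None:
            d["planted_hit_counts"] = {
                "index": self.planted_hit_counts.index.tolist(),
                "columns": self.planted_hit_counts.columns.tolist(),
                "data": self.planted_hit_counts.to_numpy().tolist(),
            }
        return d


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts with planted module, DE and composition
    structure; per-cell QC covariates mostly below the default cutoffs."""
    rng = config.rng("expression")
    g, c = config.n_genes, config.n_cells
    gene_ids = [f"gene{i:05d}" for i in range(g)]
    cell_ids = [f"cell{i:05d}" for i in range(c)]
    clusters = [f"c{i}" for i in range(config.n_clusters)]
    conditions = list(config.cluster_proportions_by_condition)

    # planted gene panels (disjoint)
    special = rng.choice(g, size=config.isg_panel_size + config.n_deg, replace=False)
    isg_idx = np.sort(special[: config.isg_panel_size])
    deg_idx = np.sort(special[config.isg_panel_size :])

    # cell labels: conditions split evenly, clusters per condition proportions
    n1 = c // 2 + c % 2
    cond_labels = np.array([conditions[0]] * n1 + [conditions[1]] * (c - n1))
    cluster_labels = np.empty(c, dtype=object)
    for cond in conditions:
        mask = cond_labels == cond
        p = np.asarray(config.cluster_proportions_by_condition[cond])
        cluster_labels[mask] = rng.choice(clusters, size=mask.sum(), p=p)

    isg_high_cluster = clusters[0]

    # gene x cell expected counts
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    effect = np.ones((g, c))
    in_high = cluster_labels == isg_high_cluster
    effect[np.ix_(isg_idx, np.flatnonzero(in_high))] *= np.exp(config.isg_shift)
    # balanced DE planting (half up per condition) keeps per-cell totals
    # comparable between conditions, avoiding compositional fold-change bias
    in_cond1 = cond_labels == conditions[0]
    half = len(deg_idx) // 2
    deg_up1, deg_up2 = deg_idx[:half], deg_idx[half:]
    effect[np.ix_(deg_up1, np.flatnonzero(in_cond1))] *= config.deg_fold
    effect[np.ix_(deg_up2, np.flatnonzero(~in_cond1))] *= config.deg_fold

    depth = config.depth_mean * rng.lognormal(mean=0.0, sigma=0.2, size=c)
    rel = weights[:, None] * effect
    rel /= rel.sum(axis=0, keepdims=True)
    mu = rel * depth[None, :]

    r = 1.0 / config.dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.int64)

    qc_rng = config.rng("qc_covariates")
    fail = qc_rng.random(c) < config.qc_fail_fraction
    mito = np.where(
        fail,
        qc_rng.uniform(0.005, 0.02, size=c),
        qc_rng.uniform(0.0, 0.004, size=c),
    )
    fail_d = qc_rng.random(c) < config.qc_fail_fraction
    doublet = np.where(
        fail_d,
        qc_rng.uniform(0.0025, 0.01, size=c),
        qc_rng.uniform(0.0, 0.002, size=c),
    )

    meta = pd.DataFrame(
        {
            "condition": cond_labels,
            "cluster": cluster_labels,
            "mito_fraction": mito,
            "doublet_score": doublet,
            "umi_total": counts.sum(axis=0),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        metadata=meta,
    )

    props = config.cluster_proportions_by_condition
    p1 = np.asarray(props[conditions[0]])
    p2 = np.asarray(props[conditions[1]])
    eps = 1e-12
    enriched = [
        clusters[i]
        for i in range(config.n_clusters)
        if abs(np.log2((p1[i] + eps) / (p2[i] + eps))) > 1.0
    ]
    truth = GroundTruth(
        isg_gene_ids=[gene_ids[i] for i in isg_idx],
        isg_high_cluster=isg_high_cluster,
        deg_gene_ids=[gene_ids[i] for i in deg_idx],
        enriched_clusters=enriched,
        extras={
            "conditions": conditions,
            "deg_up_condition": {
                gene_ids[i]: conditions[0] for i in deg_up1
            }
            | {gene_ids[i]: conditions[1] for i in deg_up2},
            "rng": "numpy PCG64, substreams [seed, stage]",
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Regulatory simulation
# ---------------------------------------------------------------------------

def _consensus_pwm(consensus: str, major: float = 0.97) -> np.ndarray:
    minor = (1.0 - major) / 3.0
    mat = np.full((len(consensus), 4), minor)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = major
    return mat


def simulate_regulatory(
    config: SimulationConfig,
) -> tuple[GenomeSequences, GeneAnnotation, PeakSet, PWMCollection, FamilyMap, GroundTruth]:
    """Background genome with tiled genes, peaks over gene bodies/promoters,
    near-deterministic PWMs and planted consensus occurrences.

    Motif consensus strings are substituted into non-overlapping positions
    at `base_plant_rate` per family block per peak, multiplied by
    `target_density_multiplier` in peaks of target genes; motifs of the same
    block co-occur with probability `co_plant_prob` given an active block.
    """
    rng = config.rng("genome")
    seqs: dict[str, np.ndarray] = {}
    for i in range(config.genome_n_seqs):
        seqs[f"chr{i + 1}"] = rng.integers(0, 4, size=config.seq_len)

    # tile genes with disjoint body+promoter territories (gap > 2 x 2 kb)
    records = []
    gid = 0
    for chrom in seqs:
        pos = 2100 + int(rng.integers(0, 200))
        while True:
            glen = int(rng.integers(400, 800))
            if pos + glen > config.seq_len - 2200:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + glen,
                    "strand": strand,
                }
            )
            gid += 1
            pos += glen + 4300 + int(rng.integers(0, 400))
    genes = GeneAnnotation(frame=pd.DataFrame(records))
    gene_ids = genes.gene_ids

    # 1-5 non-overlapping peaks per gene inside body + 2-kb promoter
    peak_rows = []
    peak_gene: list[str] = []
    pid = 0
    for rec in records:
        if rec["strand"] == "+":
            ext_lo, ext_hi = max(0, rec["start"] - 2000), rec["end"]
        else:
            ext_lo, ext_hi = rec["start"], min(config.seq_len, rec["end"] + 2000)
        n_pk = int(rng.integers(1, 6))
        pos = ext_lo + int(rng.integers(0, 100))
        for _ in range(n_pk):
            plen = int(rng.integers(200, 501))
            if pos + plen > ext_hi:
                break
            peak_rows.append(
                {
                    "peak_id": f"peak{pid:05d}",
                    "chrom": rec["chrom"],
                    "start": pos,
                    "end": pos + plen,
                }
            )
            peak_gene.append(rec["gene_id"])
            pid += 1
            pos += plen + int(rng.integers(20, 200))

    # motifs, families, blocks
    consensi = [
        "".join(_BASES[rng.integers(0, 4, size=config.motif_len)])
        for _ in range(config.n_motifs)
    ]
    motifs = PWMCollection(
        [
            Motif(
                motif_id=f"M{i:03d}",
                tf_name=f"TF{i:03d}",
                matrix=_consensus_pwm(cons),
            )
            for i, cons in enumerate(consensi)
        ]
    )
    families = [f"fam{i}" for i in range(config.n_families)]
    fam_of_motif = {
        m.motif_id: families[i % config.n_families]
        for i, m in enumerate(motifs)
    }
    family_map = FamilyMap(mapping=fam_of_motif)
    # families split into two co-occurrence blocks
    family_blocks = {
        fam: (0 if i < (config.n_families + 1) // 2 else 1)
        for i, fam in enumerate(families)
    }
    block_motifs: dict[int, list[str]] = {0: [], 1: []}
    for m in motifs:
        block_motifs[family_blocks[fam_of_motif[m.motif_id]]].append(m.motif_id)

    n_targets = max(1, int(round(config.target_fraction * len(gene_ids))))
    target_gene_ids = sorted(
        rng.choice(gene_ids, size=min(n_targets, len(gene_ids)), replace=False)
    )
    target_set = set(target_gene_ids)

    # plant consensus occurrences by substitution (never insertions)
    plant_rng = config.rng("planting")
    motif_ids = motifs.motif_ids
    midx = {m: i for i, m in enumerate(motif_ids)}
    cons_codes = {
        m.motif_id: np.array(["ACGT".index(b) for b in consensi[i]])
        for i, m in enumerate(motifs)
    }
    # Target-gene peaks: family blocks are co-planted (block activates, then
    # each member motif plants with co_plant_prob), at base_plant_rate times
    # the density multiplier. Background peaks: each motif plants
    # independently at the matched marginal rate, so no co-occurrence
    # structure exists outside target peaks and a multiplier of 1 is an
    # exact null.
    planted = np.zeros((len(peak_rows), len(motif_ids)), dtype=np.int64)
    used: dict[str, list[tuple[int, int]]] = {chrom: [] for chrom in seqs}
    base_marginal = min(config.base_plant_rate, 1.0) * config.co_plant_prob
    for pi, (prow, parent) in enumerate(zip(peak_rows, peak_gene)):
        is_target = parent in target_set
        to_plant: list[str] = []
        if is_target:
            rate = min(
                config.base_plant_rate * config.target_density_multiplier, 0.95
            )
            for members in block_motifs.values():
                if not members or plant_rng.random() >= rate:
                    continue
                for mid in members:
                    if plant_rng.random() < config.co_plant_prob:
                        to_plant.append(mid)
        else:
            for mid in motif_ids:
                if plant_rng.random() < base_marginal:
                    to_plant.append(mid)
        for mid in to_plant:
            ok = _plant(
                seqs[prow["chrom"]],
                used[prow["chrom"]],
                prow["start"],
                prow["end"],
                cons_codes[mid],
                plant_rng,
            )
            if ok:
                planted[pi, midx[mid]] += 1

    genome = GenomeSequences(
        {sid: "".join(_BASES[codes]) for sid, codes in seqs.items()}
    )
    planted_df = pd.DataFrame(
        planted,
        index=pd.Index([r["peak_id"] for r in peak_rows], name="peak_id"),
        columns=motif_ids,
    )

    # per-population accessibility: target-gene peaks more open in popA
    acc_rng = config.rng("accessibility")
    base = acc_rng.gamma(shape=2.0, scale=1.0, size=len(peak_rows))
    other = acc_rng.gamma(shape=2.0, scale=1.0, size=len(peak_rows))
    is_target_peak = np.array([pg in target_set for pg in peak_gene])
    pop_a = base * np.where(is_target_peak, config.target_accessibility_boost, 1.0)
    accessibility = pd.DataFrame(
        {"popA": pop_a, "popB": other},
        index=pd.Index([r["peak_id"] for r in peak_rows], name="peak_id"),
    )
    peaks = PeakSet(frame=pd.DataFrame(peak_rows), accessibility=accessibility)

    truth = GroundTruth(
        target_gene_ids=list(target_gene_ids),
        planted_hit_counts=planted_df,
        family_blocks=family_blocks,
        extras={
            "consensi": dict(zip(motif_ids, consensi)),
            "peak_parent_gene": dict(
                zip([r["peak_id"] for r in peak_rows], peak_gene)
            ),
            "accessible_population": "popA",
            "rng": "numpy PCG64, substreams [seed, stage]",
        },
    )
    return genome, genes, peaks, motifs, family_map, truth


def _plant(
    seq_codes: np.ndarray,
    used: list[tuple[int, int]],
    start: int,
    end: int,
    consensus: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 10,
) -> bool:
    """Substitute a consensus into [start, end) avoiding previously planted
    intervals on the chromosome; returns False if no free slot was found."""
    L = len(consensus)
    if end - start < L:
        return False
    for _ in range(max_tries):
        off = int(rng.integers(start, end - L + 1))
        if all(off + L <= a or off >= b for a, b in used):
            seq_codes[off : off + L] = consensus
            used.append((off, off + L))
            return True
    return False


# ---------------------------------------------------------------------------
# Emission of on-disk fixtures
# ---------------------------------------------------------------------------

def emit_expression(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write MTX + sidecars + metadata + ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(config)
    paths = {
        "mtx": outdir / "counts.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "metadata": outdir / "cell_metadata.tsv",
        "truth": outdir / "expression_truth.json",
    }
    io_formats.write_counts(
        matrix, paths["mtx"], paths["features"], paths["barcodes"], paths["metadata"]
    )
    io_formats.write_json(truth.to_json_dict(), paths["truth"])
    return paths


def emit_regulatory(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, gene TSV, BED, accessibility TSV, MEME, family map and
    ground-truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, peaks, motifs, family_map, truth = simulate_regulatory(config)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.tsv",
        "peaks": outdir / "peaks.bed",
        "accessibility": outdir / "accessibility.tsv",
        "motifs": outdir / "motifs.meme",
        "families": outdir / "families.tsv",
        "truth": outdir / "regulatory_truth.json",
    }
    io_formats.write_fasta(genome, paths["genome"])
    io_formats.write_gene_annotation(genes, paths["genes"])
    io_formats.write_bed_peaks(peaks, paths["peaks"], paths["accessibility"])
    io_formats.write_meme_motifs(motifs, paths["motifs"])
    io_formats.write_family_map(
        family_map, paths["families"], {m.motif_id: m.tf_name for m in motifs}
    )
    io_formats.write_json(truth.to_json_dict(), paths["truth"])
    return paths


def config_metadata(config: SimulationConfig) -> dict:
    meta = asdict(config)
    meta["rng_algorithm"] = "numpy PCG64 seeded with [seed, stage_index]"
    return meta
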