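"""Readers and writers for every on-disk format the pipeline touches.

All genomic intervals are 0-based half-open. TSV tables are UTF-8 with a
header row. The motif interchange dialect is MEME "minimal".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError

_IUPAC_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequences:
    """Ordered map of sequence id -> uppercase DNA over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"sequence {sid!r} is empty")
            bad = set(seq) - _IUPAC_DNA
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FormatError(
                    f"sequence {sid!r} has non-IUPAC character "
                    f"{seq[pos]!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.sequences

    def reverse_complement(self) -> "GenomeSequences":
        return GenomeSequences(
            {sid: seq.translate(_COMPLEMENT)[::-1] for sid, seq in self.sequences.items()}
        )


@dataclass
class GeneAnnotation:
    """Gene records with 0-based half-open coordinates and strand."""

    frame: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        f = self.frame
        if f["gene_id"].duplicated().any():
            dups = f.loc[f["gene_id"].duplicated(), "gene_id"].tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if (f["start"] >= f["end"]).any():
            raise FormatError("gene annotation has start >= end")
        if not f["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be '+' or '-'")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def gene_ids(self) -> list[str]:
        return self.frame["gene_id"].tolist()


@dataclass
class PeakSet:
    """Genomic intervals with optional per-population accessibility means."""

    frame: pd.DataFrame  # columns: peak_id, chrom, start, end
    accessibility: pd.DataFrame | None = None  # index peak_id, one column per population

    def __post_init__(self) -> None:
        f = self.frame
        for c in ("peak_id", "chrom", "start", "end"):
            if c not in f.columns:
                raise FormatError(f"peak table missing column {c!r}")
        if f["peak_id"].duplicated().any():
            raise FormatError("duplicate peak ids")
        if (f["start"] >= f["end"]).any():
            raise FormatError("peak with start >= end")
        self.frame = f.reset_index(drop=True)
        if self.accessibility is not None:
            acc = self.accessibility
            if not set(self.peak_ids).issubset(acc.index):
                raise FormatError("accessibility table missing peaks")
            if (acc.to_numpy() < 0).any():
                raise FormatError("negative accessibility value")
            self.accessibility = acc.loc[self.peak_ids]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def peak_ids(self) -> list[str]:
        return self.frame["peak_id"].tolist()

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()


@dataclass
class Motif:
    motif_id: str
    tf_name: str
    matrix: np.ndarray  # positions x 4 probabilities, columns A,C,G,T

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise FormatError(f"motif {self.motif_id}: matrix must be L x 4")
        if (m < 0).any():
            raise FormatError(f"motif {self.motif_id}: negative probability")
        sums = m.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise FormatError(f"motif {self.motif_id}: rows do not sum to 1")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PWMCollection:
    motifs: list[Motif]

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate motif ids in collection")
        self._by_id = {m.motif_id: m for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, motif_id: str) -> Motif:
        return self._by_id[motif_id]

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]


@dataclass
class FamilyMap:
    """motif_id -> TF family label."""

    mapping: dict[str, str]

    def __getitem__(self, motif_id: str) -> str:
        return self.mapping[motif_id]

    def validate_against(self, pwms: PWMCollection) -> None:
        missing = [m for m in pwms.motif_ids if m not in self.mapping]
        if missing:
            raise InputError(f"motifs without a family: {missing}")

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.mapping.values():
            seen.setdefault(fam)
        return list(seen)


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells integer counts with aligned cell metadata."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    metadata: pd.DataFrame  # index = cell_ids

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not self.metadata.index.equals(pd.Index(self.cell_ids)):
            missing = set(self.cell_ids) - set(self.metadata.index)
            if missing:
                raise FormatError(
                    f"metadata missing barcodes: {sorted(missing)[:5]}"
                )
            self.metadata = self.metadata.loc[self.cell_ids]
        if "umi_total" not in self.metadata.columns:
            self.metadata = self.metadata.assign(
                umi_total=np.asarray(self.counts.sum(axis=0)).ravel().astype(int)
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            metadata=self.metadata.iloc[idx].copy(),
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequences:
    """Read a FASTA file; uppercases sequence and joins wrapped lines.

    Raises FormatError on duplicate headers or non-IUPAC characters.
    """
    path = Path(path)
    sequences: dict[str, list[str]] = {}
    current: str | None = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                sid = line[1:].split()[0] if line[1:].split() else ""
                if not sid:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if sid in sequences:
                    raise FormatError(f"{path}: duplicate header {sid!r}")
                sequences[sid] = []
                current = sid
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                sequences[current].append(line.upper())
    joined = {sid: "".join(parts) for sid, parts in sequences.items()}
    return GenomeSequences(joined)


def write_fasta(genome: GenomeSequences, path: str | Path, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for sid, seq in genome.sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

_ROW_SUM_TOL = 1e-3


def read_meme_motifs(path: str | Path) -> PWMCollection:
    """Parse a MEME minimal-format motif file into probability matrices.

    Rows whose sum is within 1e-3 of 1 are renormalized; rows further off
    raise FormatError. The alphabet must be ACGT.
    """
    path = Path(path)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    motifs: list[Motif] = []
    i = 0
    saw_alphabet = False
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip() if "=" in line else ""
            if alpha and alpha != "ACGT":
                raise FormatError(f"{path}: alphabet {alpha!r}, expected ACGT")
            saw_alphabet = True
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without an id")
            motif_id = parts[1]
            tf_name = parts[2] if len(parts) > 2 else motif_id
            # advance to letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    break
                j += 1
            if j >= len(lines) or not lines[j].strip().startswith(
                "letter-probability"
            ):
                raise FormatError(
                    f"{path}: motif {motif_id}: missing letter-probability matrix"
                )
            rows: list[list[float]] = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL", "letter-probability")):
                    break
                vals = [float(x) for x in s.split()]
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {motif_id}: row with {len(vals)} values"
                    )
                rows.append(vals)
                j += 1
            if not rows:
                raise FormatError(f"{path}: motif {motif_id}: empty matrix")
            mat = np.array(rows, dtype=float)
            sums = mat.sum(axis=1)
            off = np.abs(sums - 1.0)
            if (off > _ROW_SUM_TOL).any():
                k = int(np.argmax(off))
                raise FormatError(
                    f"{path}: motif {motif_id}: row {k} sums to {sums[k]:.6f}, "
                    f"outside 1 +/- {_ROW_SUM_TOL}"
                )
            mat = mat / sums[:, None]
            motifs.append(Motif(motif_id=motif_id, tf_name=tf_name, matrix=mat))
            i = j - 1
        i += 1
    if not motifs:
        raise FormatError(f"{path}: no MOTIF records found")
    if not saw_alphabet:
        raise FormatError(f"{path}: missing ALPHABET declaration")
    return PWMCollection(motifs)


def write_meme_motifs(pwms: PWMCollection, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for m in pwms:
            fh.write(f"MOTIF {m.motif_id} {m.tf_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(m)} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.9f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Counts (Matrix Market + sidecars)
# ---------------------------------------------------------------------------

def read_counts(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Load a genes x cells MTX with feature/barcode sidecars and metadata."""
    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX dimensions {mat.shape} do not match sidecars "
            f"({len(genes)} features, {len(cells)} barcodes)"
        )
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        missing = [c for c in cells if c not in meta.index]
        if missing:
            raise FormatError(f"metadata missing barcodes: {missing[:5]}")
        meta = meta.loc[cells]
    else:
        meta = pd.DataFrame(index=pd.Index(cells))
    return ExpressionMatrix(
        counts=mat, gene_ids=genes, cell_ids=cells, metadata=meta
    )


def write_counts(
    matrix: ExpressionMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.counts))
    pd.Series(matrix.gene_ids).to_csv(
        features_path, sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        barcodes_path, sep="\t", header=False, index=False
    )
    if metadata_path is not None:
        matrix.metadata.to_csv(metadata_path, sep="\t", index_label="cell_id")


# ---------------------------------------------------------------------------
# BED and TSV tables
# ---------------------------------------------------------------------------

def read_bed_peaks(path: str | Path, accessibility_path: str | Path | None = None) -> PeakSet:
    """Read peaks from BED (>=4 columns: chrom, start, end, name)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise FormatError(f"{path}: BED needs >= 4 columns for named peaks")
    frame = pd.DataFrame(
        {
            "peak_id": bed[3].astype(str),
            "chrom": bed[0].astype(str),
            "start": bed[1].astype(int),
            "end": bed[2].astype(int),
        }
    )
    acc = None
    if accessibility_path is not None:
        acc = pd.read_csv(accessibility_path, sep="\t", index_col=0)
        acc.index = acc.index.astype(str)
    return PeakSet(frame=frame, accessibility=acc)


def write_bed_peaks(peaks: PeakSet, path: str | Path, accessibility_path: str | Path | None = None) -> None:
    f = peaks.frame
    out = pd.DataFrame(
        {
            0: f["chrom"],
            1: f["start"],
            2: f["end"],
            3: f["peak_id"],
            4: 0,
            5: ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
    if accessibility_path is not None and peaks.accessibility is not None:
        peaks.accessibility.to_csv(
            accessibility_path, sep="\t", index_label="peak_id"
        )


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene annotation from TSV (gene_id, chrom, start, end, strand)
    or from a minimal GTF (lines with feature == 'gene')."""
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        return _read_gtf_genes(path)
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return GeneAnnotation(frame=frame)


def _read_gtf_genes(path: Path) -> GeneAnnotation:
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = parts[8]
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip().strip('"')
                    break
            if gene_id is None:
                raise FormatError(f"{path}: gene line without gene_id attribute")
            records.append(
                {
                    "gene_id": gene_id,
                    "chrom": parts[0],
                    "start": int(parts[3]) - 1,  # GTF is 1-based inclusive
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return GeneAnnotation(frame=pd.DataFrame(records))


def write_gene_annotation(genes: GeneAnnotation, path: str | Path) -> None:
    genes.frame.to_csv(path, sep="\t", index=False)


def read_family_map(path: str | Path) -> FamilyMap:
    """TSV with columns motif_id, tf_name, family."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    for c in ("motif_id", "family"):
        if c not in t.columns:
            raise FormatError(f"{path}: family map missing column {c!r}")
    if t["motif_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate motif_id in family map")
    return FamilyMap(mapping=dict(zip(t["motif_id"], t["family"])))


def write_family_map(
    fam: FamilyMap, path: str | Path, tf_names: Mapping[str, str] | None = None
) -> None:
    rows = [
        {
            "motif_id": mid,
            "tf_name": (tf_names or {}).get(mid, mid),
            "family": family,
        }
        for mid, family in fam.mapping.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path, name: str | None = None) -> list[str]:
    """One gene id per line (first column of a TSV)."""
    t = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = t[0].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate ids in gene set")
    return ids


def write_json(obj, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    with open(path, "rt", encoding="utf-8") as fh:
        return json.load(fh)
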