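"""PWM log-odds scanning with exact p-value calibrated score thresholds.

Scores are log2-odds of the motif model versus an i.i.d. background,
discretized to integers (``granularity`` units per log2 unit). The null
distribution of the window score is computed exactly by position-wise
convolution, and the match threshold is the smallest score whose tail
probability under the background is <= the p-value cutoff. Both strands are
scanned by default; windows containing N never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ResolutionError
from .io_formats import GenomeSequences, Motif, PWMCollection, PeakSet

UNIFORM_BG = np.array([0.25, 0.25, 0.25, 0.25])

_N_SENTINEL = -(10**12)  # any window containing N scores far below threshold

_ENCODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i


@dataclass
class LogOddsMatrix:
    motif_id: str
    matrix: np.ndarray  # positions x 4, log2 odds
    background: np.ndarray
    pseudocount: float

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ScoreDistribution:
    """Exact distribution of the integer-discretized window score under the
    background model."""

    min_score: int  # integer score of the first probability entry
    probs: np.ndarray  # probs[i] = P(score == min_score + i)
    granularity: int

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.probs) - 1

    def tail(self, score_int: int) -> float:
        """P(score >= score_int)."""
        if score_int <= self.min_score:
            return 1.0
        if score_int > self.max_score:
            return 0.0
        return float(self.probs[score_int - self.min_score :].sum())


@dataclass
class MotifHitMatrix:
    counts: pd.DataFrame  # index peak_id, columns motif_id, integer counts
    hits: pd.DataFrame | None = None  # peak_id, motif_id, offset, strand, score

    @property
    def peak_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def motif_ids(self) -> list[str]:
        return self.counts.columns.tolist()


def build_logodds(
    motif: Motif,
    background: np.ndarray | None = None,
    pseudocount: float = 0.001,
) -> LogOddsMatrix:
    """log2((p + pseudocount*bg) / ((1 + pseudocount) * bg)) per position/base."""
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise InputError("background must be 4 positive frequencies")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise InputError("background frequencies must sum to 1")
    lo = np.log2((motif.matrix + pseudocount * bg) / ((1.0 + pseudocount) * bg))
    return LogOddsMatrix(
        motif_id=motif.motif_id, matrix=lo, background=bg, pseudocount=pseudocount
    )


def discretize(lo: LogOddsMatrix, granularity: int = 1000) -> np.ndarray:
    """Integer score table (positions x 4) at `granularity` units per log2."""
    return np.rint(lo.matrix * granularity).astype(np.int64)


def exact_threshold(
    lo: LogOddsMatrix,
    p_cutoff: float = 1e-4,
    granularity: int = 1000,
) -> tuple[float, ScoreDistribution]:
    """Smallest score with background tail probability <= p_cutoff.

    Returns the threshold on the log2 scale (integer threshold divided by
    granularity) plus the exact discretized score distribution. When even the
    maximum score has tail mass > p_cutoff the threshold sits one unit above
    the maximum, so no window can match.
    """
    if not 0.0 < p_cutoff < 1.0:
        raise InputError("p_cutoff must be in (0, 1)")
    sint = discretize(lo, granularity)
    span = int((sint.max(axis=1) - sint.min(axis=1)).sum())
    if span > 200_000_000:
        raise ResolutionError(
            f"motif {lo.motif_id}: score range {span} too large at "
            f"granularity {granularity}; lower the granularity"
        )
    bg = lo.background
    probs = np.array([1.0])
    min_sum = 0
    for j in range(sint.shape[0]):
        row = sint[j]
        lo_j, hi_j = int(row.min()), int(row.max())
        new = np.zeros(len(probs) + (hi_j - lo_j))
        for b in range(4):
            off = int(row[b]) - lo_j
            new[off : off + len(probs)] += probs * bg[b]
        probs = new
        min_sum += lo_j
    dist = ScoreDistribution(min_score=min_sum, probs=probs, granularity=granularity)

    # smallest s with P(score >= s) <= p_cutoff, via suffix sums
    tail = np.cumsum(probs[::-1])[::-1]
    ok = tail <= p_cutoff
    if ok.any():
        thr_int = dist.min_score + int(np.argmax(ok))
    else:
        thr_int = dist.max_score + 1
    return thr_int / granularity, dist


def _rc_table(sint: np.ndarray) -> np.ndarray:
    """Integer score table for matches on the reverse strand."""
    rc = np.empty_like(sint)
    rc[:, :4] = sint[::-1, :4][:, ::-1]
    return rc


def _window_scores(table: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Score every window of len(table) along an encoded sequence."""
    L = table.shape[0]
    n = encoded.size
    if n < L:
        return np.empty(0, dtype=np.int64)
    wins = n - L + 1
    acc = np.zeros(wins, dtype=np.int64)
    for j in range(L):
        acc += table[j][encoded[j : j + wins]]
    return acc


def scan_peaks(
    genome: GenomeSequences,
    peaks: PeakSet,
    motifs: PWMCollection,
    p_cutoff: float = 1e-4,
    both_strands: bool = True,
    background: np.ndarray | None = None,
    pseudocount: float = 0.001,
    granularity: int = 1000,
    collect_hits: bool = False,
) -> MotifHitMatrix:
    """Count threshold-passing motif matches per peak.

    Every window position on the forward (and, if both_strands, reverse)
    strand is scored; overlapping qualifying windows each count. Peaks
    shorter than the motif yield zero counts.
    """
    for chrom in peaks.frame["chrom"].unique():
        if chrom not in genome:
            raise InputError(f"peak chromosome {chrom!r} not in genome")

    encoded = {
        sid: _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for sid, seq in genome.sequences.items()
    }
    n_peaks = len(peaks)
    counts = np.zeros((n_peaks, len(motifs)), dtype=np.int64)
    records: list[dict] = []

    pframe = peaks.frame
    for mi, motif in enumerate(motifs):
        lo = build_logodds(motif, background=background, pseudocount=pseudocount)
        threshold, _ = exact_threshold(lo, p_cutoff=p_cutoff, granularity=granularity)
        thr_int = int(round(threshold * granularity))
        L = len(motif)
        sint = discretize(lo, granularity)
        # widen tables with an N column so N-containing windows never match
        fwd = np.concatenate([sint, np.full((L, 1), _N_SENTINEL, np.int64)], axis=1)
        rev = _rc_table(sint)
        rev = np.concatenate([rev, np.full((L, 1), _N_SENTINEL, np.int64)], axis=1)

        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sid, enc in encoded.items():
            f = _window_scores(fwd, enc) >= thr_int
            r = (
                _window_scores(rev, enc) >= thr_int
                if both_strands
                else np.zeros(max(enc.size - L + 1, 0), dtype=bool)
            )
            per_chrom[sid] = (f, r)

        for pi in range(n_peaks):
            chrom = pframe.at[pi, "chrom"]
            start = int(pframe.at[pi, "start"])
            end = int(pframe.at[pi, "end"])
            if end - start < L:
                continue
            f, r = per_chrom[chrom]
            stop = end - L + 1  # window starts fully inside the peak
            fhits = f[start:stop]
            rhits = r[start:stop]
            counts[pi, mi] = int(fhits.sum()) + int(rhits.sum())
            if collect_hits:
                pid = pframe.at[pi, "peak_id"]
                for off in np.flatnonzero(fhits):
                    records.append(
                        {
                            "peak_id": pid,
                            "motif_id": motif.motif_id,
                            "offset": int(off),
                            "strand": "+",
                        }
                    )
                for off in np.flatnonzero(rhits):
                    records.append(
                        {
                            "peak_id": pid,
                            "motif_id": motif.motif_id,
                            "offset": int(off),
                            "strand": "-",
                        }
                    )

    counts_df = pd.DataFrame(
        counts, index=pd.Index(peaks.peak_ids, name="peak_id"),
        columns=motifs.motif_ids,
    )
    hits_df = pd.DataFrame(records) if collect_hits else None
    return MotifHitMatrix(counts=counts_df, hits=hits_df)
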