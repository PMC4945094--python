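"""CTT-repeat motif scanning and recombination-class contingency tests.

Degenerate CTT/CCN repeats are enriched at plant crossover hotspots near
gene 5' ends.  This module scans promoter-proximal windows with a position
weight matrix (by default the degenerate PWM of a 16-mer CTT-repeat
consensus), splits genes into high/low recombination classes by the rate of
their containing map interval, and tests motif presence against class in a
2x2 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "MotifHit",
    "pwm_from_consensus",
    "pwm_from_counts",
    "scan_window",
    "extract_tss_window",
    "partition_by_rate",
    "contingency_test",
]

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over ACGT with per-position min/max."""

    matrix: np.ndarray  # (L, 4), non-negative
    built_from: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("matrix must be (L, 4) with L >= 1")
        if np.any(m < 0):
            raise ValueError("weights must be non-negative")
        if np.any(m.max(axis=1) == 0):
            raise ValueError("all-zero column in PWM")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def score(self, seq: str) -> float:
        """Raw score of one L-length sequence (non-ACGT bases score 0)."""
        if len(seq) != len(self):
            raise ValueError("sequence length != motif length")
        s = 0.0
        for i, b in enumerate(seq.upper()):
            j = _INDEX.get(b)
            if j is not None:
                s += self.matrix[i, j]
        return s


@dataclass(frozen=True)
class MotifHit:
    """A PWM match: 0-based window offset, strand, normalized identity score."""

    offset: int
    strand: str
    identity_score: float
    gene_id: str = ""


def pwm_from_consensus(consensus: str) -> PWM:
    """Degenerate PWM: weight 1 on the consensus base, 0 elsewhere.

    The normalized score of a window is then exactly the fraction of
    positions matching the consensus, so the '>= 80% identity' matching rule
    is the 0.8 score threshold.
    """
    consensus = consensus.upper()
    if set(consensus) - set(ALPHABET):
        raise ValueError("consensus must be over {A,C,G,T}")
    m = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        m[i, _INDEX[b]] = 1.0
    return PWM(m, built_from=consensus)


def pwm_from_counts(counts: np.ndarray, pseudocount: float = 0.0) -> PWM:
    """PWM from a (L, 4) count matrix, optionally with a pseudocount."""
    m = np.asarray(counts, dtype=float) + pseudocount
    return PWM(m, built_from="counts")


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else -> 4 (scores 0 via a padded PWM column)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int64)
    for b, i in _INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    L = len(pwm)
    padded = np.hstack([pwm.matrix, np.zeros((L, 1))])
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return padded[np.arange(L), win].sum(axis=1)


def scan_window(seq: str, pwm: PWM, threshold: float = 0.80,
                gene_id: str = "") -> list[MotifHit]:
    """Slide the PWM over both strands of a window.

    Scores are normalized to (S - S_min) / (S_max - S_min); every position
    (on either strand) at or above ``threshold`` is reported, overlapping
    hits included.  Minus-strand offsets refer to the forward window
    coordinate of the match's left edge.  A window shorter than the motif
    yields no hits.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    L = len(pwm)
    if len(seq) < L:
        return []
    lo, hi = pwm.min_score, pwm.max_score
    span = hi - lo
    hits: list[MotifHit] = []
    fwd = _scan_one_strand(_encode(seq), pwm)
    rev = _scan_one_strand(_encode(seq.translate(_COMP)[::-1]), pwm)
    n = len(seq)
    for strand, scores in (("+", fwd), ("-", rev)):
        norm = (scores - lo) / span
        for j in np.flatnonzero(norm >= threshold - 1e-12):
            offset = int(j) if strand == "+" else n - L - int(j)
            hits.append(MotifHit(offset=offset, strand=strand,
                                 identity_score=float(norm[j]), gene_id=gene_id))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def extract_tss_window(chrom_seq: str, tss: int, strand: str,
                       window: int = 1000, anchor: str = "tss-centered") -> str:
    """Window of sequence around a transcription start site.

    ``tss`` is 1-based.  ``anchor='tss-centered'`` takes tss +/- window/2;
    ``'tss-downstream'`` takes [tss, tss + window) in the direction of
    transcription.  Truncated silently at the chromosome ends.
    """
    if anchor == "tss-centered":
        lo = tss - window // 2
        hi = lo + window
    elif anchor == "tss-downstream":
        if strand == "-":
            lo, hi = tss - window + 1, tss + 1
        else:
            lo, hi = tss, tss + window
    else:
        raise ValueError("anchor must be 'tss-centered' or 'tss-downstream'")
    return chrom_seq[max(lo - 1, 0):min(hi - 1, len(chrom_seq))]


def partition_by_rate(genes: pd.DataFrame, interval_map: pd.DataFrame,
                      threshold_cm_per_mb: float = 4.82,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split genes into high/low recombination classes by their interval's rate.

    Each gene is assigned to the map interval containing its TSS (column
    ``tss``, 1-based; intervals are 1-based inclusive as in the interval
    map), so genes spanning an interval boundary follow their TSS.  A gene
    whose TSS falls outside the map is excluded and reported.  The
    comparison is strict: rate > threshold is 'high'.
    """
    if "tss" not in genes.columns:
        raise ValueError("genes need a 'tss' column")
    high_rows, low_rows, out_rows = [], [], []
    for _, g in genes.iterrows():
        iv = interval_map[(interval_map["chrom"] == g["chrom"]) &
                          (interval_map["start"] <= g["tss"]) &
                          (g["tss"] <= interval_map["end"])]
        if len(iv) == 0:
            out_rows.append(g)
        elif float(iv["cm_per_mb"].iloc[0]) > threshold_cm_per_mb:
            high_rows.append(g)
        else:
            low_rows.append(g)

    def frame(rows):
        return pd.DataFrame(rows).reset_index(drop=True) if rows else genes.iloc[0:0]

    return frame(high_rows), frame(low_rows), frame(out_rows)


def contingency_test(a: int, b: int, c: int, d: int,
                     correction: bool = True) -> tuple[float, float, float]:
    """2x2 chi-square test of the table [[a, b], [c, d]] with odds ratio.

    Yates continuity correction is applied by default.  Returns
    (chi2, p, odds_ratio = ad/bc).
    """
    t = np.array([[a, b], [c, d]], dtype=float)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=correction)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return float(chi2), float(p), float(odds)
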