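"""Genetic distances and crossover interval maps from double-selected backcross progeny.

A trans-hemizygous F1 carrying the two selectable insertions on opposite
homologs is backcrossed; only progeny inheriting both insertions (double
resistant) carry a crossover between them.  Because a recombinant gamete is
double resistant with probability 1/2, the genetic distance of the selected
region is

    cM = 100 * 2 * (N_dr / N_total)

with N_dr the double-resistant count and N_total all progeny screened.
Genotyping the double-resistant individuals at internal SNP markers places
each crossover into a marker interval; the per-interval counts, compared with
a null proportional to physical interval length, identify hotspot and
coldspot intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerMap",
    "CrossoverAssignment",
    "NonRecombinantError",
    "MultipleTransitionsError",
    "genetic_distance_double_selection",
    "cm_per_mb",
    "assign_crossover_interval",
    "build_interval_map",
    "global_randomness_test",
    "interval_tests",
    "bh_adjust",
    "SelectionMap",
    "SelectionMapResults",
]


class NonRecombinantError(ValueError):
    """Genotype row shows no Col<->Het transition inside the marker map."""


class MultipleTransitionsError(ValueError):
    """Genotype row shows >= 2 transitions (double crossover or call error)."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered diagnostic SNP markers on one chromosome.

    Coordinates are 1-based inclusive (TAIR convention).  ``flank_left_bp``
    and ``flank_right_bp`` are the selection-insertion coordinates bounding
    the mapped region; every marker must lie between them.
    """

    chrom: str
    ids: tuple[str, ...]
    positions: np.ndarray  # 1-based bp, strictly increasing
    col_alleles: tuple[str, ...] = ()
    ler_alleles: tuple[str, ...] = ()
    flank_left_bp: int = 0
    flank_right_bp: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size < 2:
            raise ValueError("marker map needs >= 2 markers")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if len(self.ids) != pos.size:
            raise ValueError("ids/positions length mismatch")
        left = self.flank_left_bp or int(pos[0])
        right = self.flank_right_bp or int(pos[-1])
        if not (left <= pos[0] and pos[-1] <= right):
            raise ValueError("markers must lie within the flanking insertions")
        object.__setattr__(self, "flank_left_bp", left)
        object.__setattr__(self, "flank_right_bp", right)

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    @property
    def n_intervals(self) -> int:
        """Number of elementary inter-marker intervals."""
        return self.n_markers - 1

    def interval_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) of the elementary intervals, 1-based inclusive."""
        return self.positions[:-1], self.positions[1:]

    @property
    def span_bp(self) -> int:
        return int(self.flank_right_bp - self.flank_left_bp + 1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom: str | None = None,
                   flank_left_bp: int = 0, flank_right_bp: int = 0) -> "MarkerMap":
        """Build from a table with columns (marker, chrom, pos, col_allele, ler_allele)."""
        if chrom is None:
            chroms = df["chrom"].unique()
            if len(chroms) != 1:
                raise ValueError("marker table spans several chromosomes; pass chrom=")
            chrom = str(chroms[0])
        sub = df[df["chrom"] == chrom].sort_values("pos")
        return cls(
            chrom=chrom,
            ids=tuple(sub["marker"].astype(str)),
            positions=sub["pos"].to_numpy(np.int64),
            col_alleles=tuple(sub.get("col_allele", pd.Series([], dtype=str)).astype(str)),
            ler_alleles=tuple(sub.get("ler_allele", pd.Series([], dtype=str)).astype(str)),
            flank_left_bp=flank_left_bp,
            flank_right_bp=flank_right_bp,
        )


@dataclass(frozen=True)
class CrossoverAssignment:
    """A recombinant's crossover placed between two informative markers."""

    individual_id: str
    left_marker_index: int
    right_marker_index: int

    @property
    def n_elementary(self) -> int:
        return self.right_marker_index - self.left_marker_index

    @property
    def interval_index(self) -> int | None:
        """Elementary interval index if the assignment is single-interval."""
        if self.n_elementary == 1:
            return self.left_marker_index
        return None


def genetic_distance_double_selection(n_double_resistant: int, n_total: int) -> tuple[float, float]:
    """Genetic distance (cM) of a double-selected region, with binomial SE.

    cM = 100 * 2 * (n_double_resistant / n_total).  The SE is the binomial
    standard error of the double-resistant proportion propagated through the
    factor 200.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_double_resistant <= n_total:
        raise ValueError("need 0 <= n_double_resistant <= n_total")
    p = n_double_resistant / n_total
    cm = 200.0 * p
    se = 200.0 * float(np.sqrt(p * (1.0 - p) / n_total))
    return cm, se


def cm_per_mb(cm: float, span_mb: float) -> float:
    """Recombination rate in cM/Mb over a physical span in Mb."""
    if span_mb <= 0:
        raise ValueError("span_mb must be positive")
    return cm / span_mb


def assign_crossover_interval(genotype_row: Sequence[str] | pd.Series,
                              marker_map: MarkerMap,
                              individual_id: str = "") -> CrossoverAssignment:
    """Locate the single Col<->heterozygous transition in one genotype row.

    ``genotype_row`` holds one call per marker: 'C' (Col homozygote),
    'H' (heterozygote) or 'N' (missing).  The crossover interval is bounded
    by the closest informative markers flanking the transition, so missing
    calls widen the interval.  Zero transitions raise
    :class:`NonRecombinantError`; two or more raise
    :class:`MultipleTransitionsError`.
    """
    calls = np.asarray(list(genotype_row), dtype="U1")
    if calls.size != marker_map.n_markers:
        raise ValueError("genotype row length != number of markers")
    informative = np.flatnonzero(calls != "N")
    if informative.size < 2:
        raise ValueError("need >= 2 non-missing calls")
    vals = calls[informative]
    switch = np.flatnonzero(vals[:-1] != vals[1:])
    if switch.size == 0:
        raise NonRecombinantError(f"{individual_id or 'row'}: non-recombinant in region")
    if switch.size > 1:
        raise MultipleTransitionsError(
            f"{individual_id or 'row'}: {switch.size} transitions (QC fail)")
    j = int(switch[0])
    return CrossoverAssignment(
        individual_id=individual_id,
        left_marker_index=int(informative[j]),
        right_marker_index=int(informative[j + 1]),
    )


def assign_all(genotypes: pd.DataFrame, marker_map: MarkerMap) -> tuple[list[CrossoverAssignment], pd.DataFrame]:
    """Assign every genotype row; QC failures are collected, not raised.

    Returns (assignments, qc) where ``qc`` is a per-category summary counting
    assigned / non_recombinant / multiple_transitions / too_few_calls rows.
    """
    out: list[CrossoverAssignment] = []
    counts = {"assigned": 0, "non_recombinant": 0,
              "multiple_transitions": 0, "too_few_calls": 0}
    for ind, row in genotypes.iterrows():
        try:
            out.append(assign_crossover_interval(row.to_numpy(), marker_map, str(ind)))
            counts["assigned"] += 1
        except NonRecombinantError:
            counts["non_recombinant"] += 1
        except MultipleTransitionsError:
            counts["multiple_transitions"] += 1
        except ValueError:
            counts["too_few_calls"] += 1
    qc = pd.DataFrame({"category": list(counts), "n": list(counts.values())})
    return out, qc


def _interval_counts(assignments: Sequence[CrossoverAssignment],
                     marker_map: MarkerMap,
                     wide: str = "fractional") -> np.ndarray:
    """Per elementary-interval crossover counts.

    Assignments widened by missing calls span several elementary intervals;
    ``wide='fractional'`` distributes their unit weight proportionally to
    interval length, ``'drop'`` discards them, ``'error'`` raises.
    """
    starts, ends = marker_map.interval_bounds()
    lengths = (ends - starts).astype(float)
    counts = np.zeros(marker_map.n_intervals, dtype=float)
    for a in assignments:
        lo, hi = a.left_marker_index, a.right_marker_index
        if hi - lo == 1:
            counts[lo] += 1.0
        elif wide == "fractional":
            w = lengths[lo:hi]
            counts[lo:hi] += w / w.sum()
        elif wide == "drop":
            continue
        else:
            raise ValueError(f"{a.individual_id}: assignment spans {hi - lo} intervals")
    return counts


def build_interval_map(assignments: Sequence[CrossoverAssignment],
                       marker_map: MarkerMap,
                       n_total_screened: int,
                       n_double_resistant: int,
                       wide: str = "fractional") -> pd.DataFrame:
    """Interval map table: counts, cM and cM/Mb per marker interval.

    Total map cM comes from the full screen via the double-selection formula
    and is distributed over intervals proportionally to the genotyped
    subset's counts, so the per-interval centimorgans sum to the total.
    """
    if len(assignments) == 0:
        raise ValueError("no crossover assignments")
    total_cm, _ = genetic_distance_double_selection(n_double_resistant, n_total_screened)
    starts, ends = marker_map.interval_bounds()
    counts = _interval_counts(assignments, marker_map, wide=wide)
    n_used = counts.sum()
    lengths = (ends - starts).astype(float)  # bp between marker midpoints
    cm = total_cm * counts / n_used
    return pd.DataFrame({
        "chrom": marker_map.chrom,
        "start": starts,
        "end": ends,
        "length_bp": lengths.astype(np.int64),
        "count": counts,
        "cm": cm,
        "cm_per_mb": cm / (lengths / 1e6),
    })


def global_randomness_test(counts: np.ndarray, lengths_bp: np.ndarray,
                           df: int | None = None) -> tuple[float, int, float]:
    """2 x n chi-square test of interval counts against length-proportional expectation.

    An interval twice as long is expected to receive twice as many
    crossovers.  ``df`` defaults to n_intervals - 1; the paper-style
    convention df = n_markers (intervals + flanks) can be passed explicitly.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if counts.size < 2:
        raise ValueError("need >= 2 intervals")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotyped crossovers")
    expected = n * lengths / lengths.sum()
    if np.any(expected <= 0):
        raise ValueError("zero expected count (zero-length interval?)")
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    dof = int(df) if df is not None else counts.size - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p


def interval_tests(counts: np.ndarray, lengths_bp: np.ndarray,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-interval 2x2 chi-square hotspot/coldspot tests with BH correction.

    For each interval the observed (count, rest) pair is compared with the
    length-proportional expectation (E_i, N - E_i) by a 1-df Pearson
    chi-square (no continuity correction: the expected row is model-derived,
    not a second sample).  p-values are Benjamini-Hochberg adjusted across
    intervals.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotyped crossovers")
    expected = n * lengths / lengths.sum()
    if np.any(expected <= 0) or np.any(expected >= n):
        raise ValueError("degenerate expected counts")
    chi2 = (counts - expected) ** 2 / expected + (counts - expected) ** 2 / (n - expected)
    p = stats.chi2.sf(chi2, 1)
    return pd.DataFrame({
        "count": counts,
        "expected": expected,
        "chi2": chi2,
        "p": p,
        "p_adj": bh_adjust(p),
        "direction": np.where(counts >= expected, "higher", "lower"),
        "significant": bh_adjust(p) < alpha,
    })


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SelectionMap:
    """Model: crossover interval map from a double-selection screen.

    Parameters
    ----------
    genotypes : DataFrame, individuals x markers, values 'C'/'H'/'N'
    marker_map : MarkerMap
    n_total_screened : all backcross progeny screened on selection plates
    n_double_resistant : progeny surviving double selection
    """

    genotypes: pd.DataFrame
    marker_map: MarkerMap
    n_total_screened: int
    n_double_resistant: int
    wide: str = "fractional"

    def fit(self, alpha: float = 0.05, df: int | None = None) -> "SelectionMapResults":
        assignments, qc = assign_all(self.genotypes, self.marker_map)
        if not assignments:
            raise ValueError("no assignable recombinants")
        intervals = build_interval_map(
            assignments, self.marker_map,
            self.n_total_screened, self.n_double_resistant, wide=self.wide)
        tests = interval_tests(intervals["count"].to_numpy(),
                               intervals["length_bp"].to_numpy(), alpha=alpha)
        intervals = pd.concat(
            [intervals, tests[["chi2", "p", "p_adj", "direction", "significant"]]], axis=1)
        chi2, dof, p = global_randomness_test(
            intervals["count"].to_numpy(), intervals["length_bp"].to_numpy(), df=df)
        total_cm, total_se = genetic_distance_double_selection(
            self.n_double_resistant, self.n_total_screened)
        return SelectionMapResults(
            model=self, intervals=intervals, qc=qc, assignments=assignments,
            total_cm=total_cm, total_cm_se=total_se,
            global_chi2=chi2, global_df=dof, global_p=p, alpha=alpha)


@dataclass
class SelectionMapResults:
    """Fitted interval map with hotspot/coldspot tests."""

    model: SelectionMap
    intervals: pd.DataFrame
    qc: pd.DataFrame
    assignments: list[CrossoverAssignment] = field(repr=False, default_factory=list)
    total_cm: float = 0.0
    total_cm_se: float = 0.0
    global_chi2: float = 0.0
    global_df: int = 0
    global_p: float = 1.0
    alpha: float = 0.05

    @property
    def n_genotyped(self) -> int:
        return len(self.assignments)

    @property
    def mean_cm_per_mb(self) -> float:
        span_mb = self.model.marker_map.span_bp / 1e6
        return cm_per_mb(self.total_cm, span_mb)

    def summary(self) -> str:
        mm = self.model.marker_map
        n_sig = int(self.intervals["significant"].sum())
        lines = [
            "Double-selection crossover map",
            "==============================",
            f"chromosome            {mm.chrom}",
            f"region span           {mm.span_bp / 1e6:.2f} Mb",
            f"screened / resistant  {self.model.n_total_screened} / {self.model.n_double_resistant}",
            f"genetic distance      {self.total_cm:.2f} cM (SE {self.total_cm_se:.2f})",
            f"mean rate             {self.mean_cm_per_mb:.2f} cM/Mb",
            f"genotyped recombinants {self.n_genotyped}",
            f"marker intervals      {len(self.intervals)}",
            f"global randomness     X2 = {self.global_chi2:.2f}, d.f. = {self.global_df}, "
            f"P = {self.global_p:.3g}",
            f"significant intervals {n_sig} at BH alpha = {self.alpha}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", index=False)

    def to_bed(self, path) -> None:
        """BED6 export, 0-based half-open, cM/Mb in the score field."""
        bed = pd.DataFrame({
            "chrom": self.intervals["chrom"],
            "start": self.intervals["start"] - 1,
            "end": self.intervals["end"],
            "name": [f"iv{i}" for i in range(len(self.intervals))],
            "score": self.intervals["cm_per_mb"].round(3),
            "strand": ".",
        })
        bed.to_csv(path, sep="\t", index=False, header=False)

    def plot(self, ax=None):
        """Step plot of cM/Mb along the region."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        mid = (self.intervals["start"] + self.intervals["end"]) / 2e6
        ax.step(mid, self.intervals["cm_per_mb"], where="mid")
        ax.set_xlabel(f"{self.model.marker_map.chrom} position (Mb)")
        ax.set_ylabel("cM/Mb")
        return ax
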