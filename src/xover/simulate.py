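"""Synthetic data with known truth for every analysis in the package.

The generators emulate the statistical structure of a Col/Ler double-selection
backcross experiment: a piecewise-constant crossover rate map over a
chromosome arm, double-resistant backcross progeny genotyped at SNP markers,
sonicated crossover-amplicon read pairs, clustered gene annotations,
four-class fluorescent pollen counts and limiting-dilution PCR titrations.
All randomness flows through one explicitly passed seed / numpy Generator;
a fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mapping import MarkerMap

__all__ = [
    "TrueRateMap",
    "SimConfig",
    "SyntheticTruth",
    "SimulatedReadPair",
    "simulate_backcross",
    "simulate_read_pairs",
    "simulate_clustered_genes",
    "simulate_pollen_counts",
    "simulate_titration",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class TrueRateMap:
    """Piecewise-constant crossover rate map (ground truth for simulation).

    ``starts``/``ends`` are 1-based inclusive, contiguous and sorted;
    ``rates`` are cM/Mb.  ``total_cm`` must stay below 50 so the region-wide
    recombinant fraction total_cm/100 is a valid single-crossover
    probability for a backcross gamete.
    """

    starts: np.ndarray
    ends: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=np.int64)
        e = np.asarray(self.ends, dtype=np.int64)
        r = np.asarray(self.rates, dtype=float)
        if not (s.size == e.size == r.size) or s.size == 0:
            raise ValueError("starts/ends/rates must be equal-length, non-empty")
        if np.any(e < s):
            raise ValueError("interval end < start")
        if np.any(s[1:] != e[:-1] + 1):
            raise ValueError("intervals must be contiguous and sorted")
        if np.any(r < 0):
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "ends", e)
        object.__setattr__(self, "rates", r)
        if self.total_cm > 50:
            raise ValueError("total_cm > 50 breaks the single-region backcross assumption")

    @property
    def lengths_bp(self) -> np.ndarray:
        return self.ends - self.starts + 1

    @property
    def interval_cm(self) -> np.ndarray:
        return self.rates * self.lengths_bp / 1e6

    @property
    def total_cm(self) -> float:
        return float(self.interval_cm.sum())

    @property
    def span(self) -> tuple[int, int]:
        return int(self.starts[0]), int(self.ends[-1])

    def locate(self, positions_bp: np.ndarray) -> np.ndarray:
        """Index of the interval containing each 1-based position."""
        pos = np.asarray(positions_bp, dtype=np.int64)
        idx = np.searchsorted(self.ends, pos, side="left")
        lo, hi = self.span
        if np.any((pos < lo) | (pos > hi)):
            raise ValueError("position outside rate map span")
        return idx

    @classmethod
    def uniform(cls, start: int, end: int, n_intervals: int, total_cm: float) -> "TrueRateMap":
        edges = np.linspace(start - 1, end, n_intervals + 1).astype(np.int64)
        starts, ends = edges[:-1] + 1, edges[1:]
        rate = total_cm / ((end - start + 1) / 1e6)
        return cls(starts, ends, np.full(n_intervals, rate))

    def with_multiplier(self, interval_index: int, fold: float,
                        keep_total: bool = True) -> "TrueRateMap":
        """Scale one interval's rate (a hotspot or coldspot).

        With ``keep_total`` the remaining intervals are rescaled so the map's
        total centimorgans is unchanged.
        """
        rates = self.rates.copy()
        lengths = self.lengths_bp
        old_total = self.total_cm
        rates[interval_index] *= fold
        if keep_total:
            others = np.ones(rates.size, dtype=bool)
            others[interval_index] = False
            rest_cm = old_total - rates[interval_index] * lengths[interval_index] / 1e6
            cur = (rates[others] * lengths[others]).sum() / 1e6
            if rest_cm <= 0 or cur <= 0:
                raise ValueError("hotspot absorbs the whole map")
            rates[others] *= rest_cm / cur
        return TrueRateMap(self.starts, self.ends, rates)


@dataclass(frozen=True)
class SimConfig:
    """Knobs for read-pair library simulation.

    Defaults mirror the pollen-typing sequencing design: 75 bp paired-end
    reads from 300-400 bp sonication fragments of a ~9.4 kb amplicon.
    """

    seed: int = 0
    n_progeny: int = 9016
    n_markers: int = 94
    n_read_pairs: int = 10_000
    read_len: int = 75
    frag_len_mean: float = 350.0
    frag_len_sd: float = 35.0
    snp_density: float = 4.0  # SNPs per kb
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_progeny", "n_markers", "n_read_pairs", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.per_base_error < 0.05:
            raise ValueError("per_base_error must lie in [0, 0.05)")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated backcross screen."""

    rate_map: TrueRateMap
    n_total: int
    n_recombinant: int
    n_double_resistant: int
    crossover_positions: np.ndarray  # bp, one per double-resistant individual
    genotyped_ids: list[str] = field(default_factory=list)
    gene_truth: pd.DataFrame | None = None

    @property
    def true_total_cm(self) -> float:
        return self.rate_map.total_cm


def sample_crossover_positions(rate_map: TrueRateMap, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Crossover breakpoints: interval ~ rate x length, position uniform within."""
    w = rate_map.interval_cm
    if w.sum() == 0:
        return np.empty(0, dtype=np.int64)
    idx = rng.choice(w.size, size=n, p=w / w.sum())
    # breakpoint after base x; x uniform over [start, end-1] of its interval
    lo = rate_map.starts[idx]
    hi = np.maximum(rate_map.ends[idx] - 1, lo)
    return rng.integers(lo, hi + 1)


def simulate_backcross(rate_map: TrueRateMap, marker_map: MarkerMap,
                       n_total: int, seed,
                       n_genotyped: int | None = None,
                       missing_rate: float = 0.0,
                       ler_side: str = "left") -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a double-selection backcross screen.

    Each gamete is recombinant in the selected region with probability
    total_cm/100 (at most one crossover, a good approximation for the
    <= ~23 cM regions this design targets), and a recombinant is recovered
    as double resistant with probability 1/2.  Crossover positions are drawn
    proportionally to rate x interval length; genotype calls are
    heterozygous on the Ler-insertion side of the breakpoint and
    Col-homozygous on the other.

    Returns the genotype matrix (genotyped double-resistant individuals x
    markers, values C/H/N) and the :class:`SyntheticTruth`.
    """
    if rate_map.total_cm >= 50:
        raise ValueError("total_cm >= 50: recombinant-fraction interpretation breaks")
    rng = _rng(seed)
    r = rate_map.total_cm / 100.0
    n_recomb = int(rng.binomial(n_total, r))
    n_dr = int(rng.binomial(n_recomb, 0.5))
    xo = np.sort(sample_crossover_positions(rate_map, n_dr, rng))
    if n_genotyped is None or n_genotyped >= n_dr:
        geno_idx = np.arange(n_dr)
    else:
        geno_idx = np.sort(rng.choice(n_dr, size=n_genotyped, replace=False))
    ids = [f"dr{i:05d}" for i in geno_idx]
    pos = marker_map.positions
    calls = np.empty((geno_idx.size, pos.size), dtype="U1")
    for row, i in enumerate(geno_idx):
        het = pos <= xo[i] if ler_side == "left" else pos > xo[i]
        calls[row] = np.where(het, "H", "C")
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = "N"
    genotypes = pd.DataFrame(calls, index=ids, columns=list(marker_map.ids))
    truth = SyntheticTruth(rate_map=rate_map, n_total=n_total,
                           n_recombinant=n_recomb, n_double_resistant=n_dr,
                           crossover_positions=xo, genotyped_ids=ids)
    return genotypes, truth


@dataclass(frozen=True)
class SimulatedReadPair:
    """One simulated crossover-fragment read pair plus its truth."""

    pair_id: str
    seq1: str
    seq2: str
    strand1: str
    strand2: str
    crossover_bp: int  # breakpoint after this template base
    frag_start: int
    frag_end: int
    n_errors: int


def simulate_read_pairs(template, crossover_positions: Sequence[int],
                        config: SimConfig, seed) -> tuple[list[SimulatedReadPair], pd.DataFrame]:
    """Simulate paired-end reads from sonicated crossover amplification products.

    Every molecule is a Ler(left)|Col(right) chimera of the amplicon around
    its crossover breakpoint (the configuration the crossover allele-specific
    PCR amplifies).  Fragment lengths are Normal(frag_len_mean, frag_len_sd)
    truncated to [2*read_len, amplicon length]; each fragment spans its
    breakpoint and yields one read per end on opposite strands.  Substitution
    errors are injected at ``per_base_error``.

    ``template`` is a :class:`~xover.pollen.AmpliconTemplate`.
    Returns the read pairs and a truth table indexed by pair id.
    """
    rng = _rng(seed)
    L = len(template.col_seq)
    rl = config.read_len
    if 2 * rl > L:
        raise ValueError("read_len too large for the amplicon")
    xo = np.asarray(crossover_positions, dtype=np.int64)
    smin, smax = int(template.snps["pos"].iloc[0]), int(template.snps["pos"].iloc[-1])
    if np.any((xo < smin) | (xo >= smax)):
        raise ValueError("crossover positions must lie between the outermost SNPs")
    which = rng.integers(0, xo.size, size=config.n_read_pairs)
    frag_lens = np.clip(
        np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, config.n_read_pairs)),
        2 * rl, L).astype(np.int64)
    pairs: list[SimulatedReadPair] = []
    rows = []
    ler, col = template.ler_seq, template.col_seq
    for i in range(config.n_read_pairs):
        x = int(xo[which[i]])
        fl = int(frag_lens[i])
        if fl > rl and rl <= L:
            fl = min(fl, L)
        lo = max(1, x - fl + 1)
        hi = min(x, L - fl + 1)
        s = int(rng.integers(lo, hi + 1)) if hi >= lo else max(1, min(x, L - fl + 1))
        e = s + fl - 1
        chim = ler[s - 1:x] + col[x:e]
        r1, r2 = chim[:rl], revcomp(chim[-rl:])
        nerr = 0
        if config.per_base_error > 0:
            r1, n1 = _inject_errors(r1, config.per_base_error, rng)
            r2, n2 = _inject_errors(r2, config.per_base_error, rng)
            nerr = n1 + n2
        pid = f"pair{i:06d}"
        pairs.append(SimulatedReadPair(pid, r1, r2, "+", "-", x, s, e, nerr))
        rows.append((pid, x, s, e, nerr))
    truth = pd.DataFrame(rows, columns=["pair_id", "crossover_bp", "frag_start",
                                        "frag_end", "n_errors"]).set_index("pair_id")
    return pairs, truth


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode(), int(hits.size)


def write_fastq_pair(pairs: Sequence[SimulatedReadPair], path1, path2,
                     qual_char: str = "I") -> None:
    """Write the two read files (Phred+33, constant quality)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{qual_char * len(p.seq1)}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{qual_char * len(p.seq2)}\n")


def simulate_clustered_genes(chrom_len: int, n_clusters: int, genes_per_cluster: int,
                             width_dist: Callable[[np.random.Generator, int], np.ndarray] | None,
                             seed,
                             spacing_scale: float = 4000.0,
                             n_background: int = 0,
                             chrom: str = "sim1") -> pd.DataFrame:
    """Clustered gene annotations plus an unclustered background set.

    Cluster anchors are uniform on the chromosome; within a cluster,
    successive gene starts are exponentially spaced (scale
    ``spacing_scale``); widths come from ``width_dist(rng, n)`` (default:
    lognormal with ~3 kb median, NBS-LRR-sized).  Overlapping genes are
    resolved by shifting right, never dropped.  Coordinates are 0-based
    half-open (BED convention) for direct use by the overlap analyses.
    """
    rng = _rng(seed)
    if width_dist is None:
        width_dist = lambda g, n: np.rint(g.lognormal(np.log(3000.0), 0.4, n)).astype(np.int64)
    records = []
    n_clustered = n_clusters * genes_per_cluster
    widths = np.maximum(width_dist(rng, n_clustered + n_background), 1)
    if widths.sum() >= chrom_len:
        raise ValueError("total gene span must be smaller than chrom_len")
    k = 0
    anchors = np.sort(rng.integers(0, chrom_len, size=n_clusters))
    for c, anchor in enumerate(anchors):
        gaps = rng.exponential(spacing_scale, genes_per_cluster)
        starts = anchor + np.cumsum(gaps).astype(np.int64)
        for s in starts:
            records.append([int(s), int(widths[k]), f"clust{c}_g{k}", "clustered"])
            k += 1
    for j in range(n_background):
        s = int(rng.integers(0, chrom_len))
        records.append([s, int(widths[k]), f"bg_g{j}", "background"])
        k += 1
    genes = pd.DataFrame(records, columns=["start", "width", "gene_id", "group"])
    out = []
    for group, sub in genes.groupby("group"):
        sub = sub.sort_values("start").reset_index(drop=True)
        rows, prev_end = [], 0
        for _, g in sub.iterrows():
            s = max(int(g["start"]), prev_end)  # shift right off the previous gene
            e = s + int(g["width"])
            prev_end = e
            rows.append([chrom, s, e, g["gene_id"], group])
        if prev_end > chrom_len:
            # a cluster ran past the end: shift the whole group back left
            shift = prev_end - chrom_len
            if rows[0][1] - shift < 0:
                raise ValueError("genes do not fit on the chromosome")
            rows = [[c, s - shift, e - shift, gid, grp] for c, s, e, gid, grp in rows]
        out.extend(rows)
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "gene_id", "group"])
    return df.sort_values(["group", "start"]).reset_index(drop=True)


def simulate_pollen_counts(true_cm: float, n_pollen: int, seed) -> dict[str, int]:
    """Four-class fluorescent pollen counts at a known genetic distance.

    A grain is recombinant with probability true_cm/100; recombinants split
    1:1 into yellow-alone and red-alone, non-recombinants 1:1 into
    both-colors and no-color.
    """
    if not 0 <= true_cm <= 50:
        raise ValueError("true_cm must lie in [0, 50]")
    rng = _rng(seed)
    r = true_cm / 100.0
    probs = [r / 2, r / 2, (1 - r) / 2, (1 - r) / 2]
    y, red, ry, none = rng.multinomial(n_pollen, probs)
    return {"yellow_only": int(y), "red_only": int(red),
            "red_and_yellow": int(ry), "none": int(none)}


def simulate_titration(conc_per_ul: float, dilution_series: Sequence[float],
                       n_reactions_per_dilution: int, seed) -> pd.DataFrame:
    """Limiting-dilution PCR: positive wells per input volume.

    A reaction receiving volume v is positive iff it contains >= 1 molecule,
    i.e. with probability 1 - exp(-conc * v).
    """
    if conc_per_ul <= 0:
        raise ValueError("conc_per_ul must be positive")
    rng = _rng(seed)
    rows = []
    for v in dilution_series:
        p = 1.0 - np.exp(-conc_per_ul * v)
        rows.append((float(v), int(rng.binomial(n_reactions_per_dilution, p)),
                     n_reactions_per_dilution))
    return pd.DataFrame(rows, columns=["input_volume", "n_positive", "n_total"])


def simulate_amplicon(length: int = 9419, n_snps: int = 40, seed=0,
                      gc: float = 0.36, chrom: str = "amp1", offset_bp: int = 1):
    """Random two-haplotype amplicon template with a given SNP count.

    Emulates a pollen-typing amplicon: ~10 kb with ~40 Col/Ler SNPs at
    Arabidopsis-like GC content.  SNPs sit on a jittered regular grid
    (spacing +/- 40%), kept >= 20 bp apart and away from the amplicon ends,
    emulating the fairly even polymorphism density of a Col/Ler amplicon
    without SNP deserts wider than a sequencing fragment.
    """
    from .pollen import AmpliconTemplate

    rng = _rng(seed)
    at = (1 - gc) / 2
    col = "".join(rng.choice(list("ACGT"), size=length,
                             p=[at, gc / 2, gc / 2, at]))
    lo, hi = 100, length - 100
    grid = np.linspace(lo, hi, n_snps)
    spacing = (hi - lo) / max(n_snps - 1, 1)
    pos_arr = grid + rng.uniform(-0.4 * spacing, 0.4 * spacing, size=n_snps)
    pos_arr = np.clip(np.sort(pos_arr), lo, hi).astype(np.int64)
    for i in range(1, n_snps):  # enforce the minimum spacing left to right
        if pos_arr[i] - pos_arr[i - 1] < 20:
            pos_arr[i] = pos_arr[i - 1] + 20
    pos = [int(p) for p in np.clip(pos_arr, lo, hi)]
    ler = list(col)
    for p in pos:
        alt = [b for b in "ACGT" if b != col[p - 1]]
        ler[p - 1] = alt[int(rng.integers(0, 3))]
    return AmpliconTemplate.from_sequences(col, "".join(ler), chrom=chrom,
                                           offset_bp=offset_bp)


def marker_map_for(rate_map: TrueRateMap, n_markers: int, chrom: str = "sim1") -> MarkerMap:
    """Evenly spaced diagnostic markers spanning a rate map."""
    lo, hi = rate_map.span
    pos = np.unique(np.linspace(lo, hi, n_markers).astype(np.int64))
    return MarkerMap(chrom=chrom, ids=tuple(f"m{i:03d}" for i in range(pos.size)),
                     positions=pos, flank_left_bp=lo, flank_right_bp=hi)
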