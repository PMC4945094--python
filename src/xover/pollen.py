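"""Pollen-typing: crossover quantification within a single amplicon.

Allele-specific PCR on F1 pollen DNA amplifies either parental or crossover
molecules from a 5-10 kb amplicon.  Limiting-dilution titration gives the
concentration of each molecule class via the Poisson zero term, and their
ratio gives the amplicon genetic distance.  Crossover breakpoints are then
located either by Sanger sequencing single molecules, or at scale by
paired-end sequencing of mass-amplified crossover molecules: each read is
placed by exact full-length matching against the two parental haplotype
sequences, pairs are pushed through an attrition filter cascade
(Mapped / Unique / Matched / Orientate / Strand), and each surviving pair
distributes one crossover's unit weight over the SNP-delimited sub-intervals
of its uncertainty gap, 1/d per bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AmpliconTemplate",
    "TitrationResult",
    "ReadEnd",
    "ReadPairRecord",
    "IntervalProfile",
    "ComplexMoleculeError",
    "poisson_concentration",
    "estimate_concentration",
    "pollen_cm",
    "classify_read",
    "classify_pairs",
    "filter_crossover_pairs",
    "fractional_interval_assignment",
    "sanger_crossover_interval",
    "aggregate_sanger",
    "CrossoverAmplicon",
    "CrossoverProfileResults",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ComplexMoleculeError(ValueError):
    """Sanger haplotype calls switch more than once along the molecule."""


@dataclass(frozen=True)
class AmpliconTemplate:
    """Two parental haplotype sequences of one amplicon plus its SNP table.

    The haplotypes are held in a common, indel-free coordinate system
    (pollen-typing primers flank any indels, which are normalized out when
    the template is built); base 1 of the template corresponds to genomic
    coordinate ``offset_bp`` on ``chrom``.  ``snps`` has 1-based template
    columns (pos, col_allele, ler_allele).
    """

    chrom: str
    offset_bp: int
    col_seq: str
    ler_seq: str
    snps: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.col_seq) != len(self.ler_seq):
            raise ValueError(
                "haplotype sequences differ in length; indels must be normalized "
                "out of the template coordinate system")
        snps = self.snps.sort_values("pos").reset_index(drop=True)
        object.__setattr__(self, "snps", snps)
        if len(snps) < 2:
            raise ValueError("amplicon template needs >= 2 SNPs")
        pos = snps["pos"].to_numpy()
        diff = np.array([i + 1 for i, (a, b) in
                         enumerate(zip(self.col_seq, self.ler_seq)) if a != b])
        if not np.array_equal(np.sort(pos), diff):
            raise ValueError("sequences must differ exactly at the SNP positions")

    def __len__(self) -> int:
        return len(self.col_seq)

    @property
    def snp_positions(self) -> np.ndarray:
        return self.snps["pos"].to_numpy(np.int64)

    @classmethod
    def from_sequences(cls, col_seq: str, ler_seq: str, chrom: str = "amp",
                       offset_bp: int = 1,
                       annotations: pd.DataFrame | None = None) -> "AmpliconTemplate":
        """Build a template deriving the SNP table from the sequence mismatches."""
        col_seq, ler_seq = col_seq.upper(), ler_seq.upper()
        if len(col_seq) != len(ler_seq):
            raise ValueError(
                "haplotype sequences differ in length; indels must be normalized "
                "out of the template coordinate system")
        rows = [(i + 1, a, b) for i, (a, b) in enumerate(zip(col_seq, ler_seq)) if a != b]
        snps = pd.DataFrame(rows, columns=["pos", "col_allele", "ler_allele"])
        return cls(chrom=chrom, offset_bp=offset_bp, col_seq=col_seq,
                   ler_seq=ler_seq, snps=snps, annotations=annotations)


def poisson_concentration(n_positive: int, n_total: int,
                          input_volume: float) -> tuple[float, tuple[float, float]]:
    """Molecules per unit volume from a limiting-dilution assay.

    With molecules Poisson-distributed across reactions, a reaction
    receiving volume v is negative with probability exp(-lambda v), so
    lambda = -ln(1 - n_positive/n_total) / v.  The confidence interval is
    the exact (Clopper-Pearson) binomial interval on the positive fraction,
    transformed through the same map.
    """
    if input_volume <= 0:
        raise ValueError("input_volume must be positive")
    if not 0 <= n_positive <= n_total or n_total == 0:
        raise ValueError("need 0 <= n_positive <= n_total, n_total > 0")
    if n_positive == n_total:
        raise ValueError(
            "all reactions positive: concentration estimate is infinite; "
            "dilute the template and repeat")
    lam = -np.log((n_total - n_positive) / n_total) / input_volume
    ci = stats.binomtest(n_positive, n_total).proportion_ci(confidence_level=0.95,
                                                            method="exact")
    lo = -np.log1p(-ci.low) / input_volume
    hi = (np.inf if ci.high >= 1.0 else -np.log1p(-ci.high) / input_volume)
    return float(lam), (float(lo), float(hi))


@dataclass(frozen=True)
class TitrationResult:
    """Concentration estimate pooled across a dilution series."""

    table: pd.DataFrame  # input_volume, n_positive, n_total
    concentration: float  # molecules per unit volume
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        t = self.table
        if ((t["n_positive"] < 0) | (t["n_positive"] > t["n_total"])).any():
            raise ValueError("need 0 <= n_positive <= n_total per dilution")


def estimate_concentration(table: pd.DataFrame) -> TitrationResult:
    """Maximum-likelihood concentration from a multi-dilution titration.

    ``table`` needs columns (input_volume, n_positive, n_total).  The
    log-likelihood is sum_i [k_i log(1 - e^(-lambda v_i)) - (n_i - k_i)
    lambda v_i]; the 95% CI comes from the profile likelihood (chi-square
    cutoff 3.84).  A single-dilution table reduces to
    :func:`poisson_concentration`.
    """
    v = table["input_volume"].to_numpy(float)
    k = table["n_positive"].to_numpy(float)
    n = table["n_total"].to_numpy(float)
    if np.any(v <= 0):
        raise ValueError("input volumes must be positive")
    if np.all(k == n):
        raise ValueError(
            "all reactions positive at every dilution: estimate infinite; dilute")
    if np.all(k == 0):
        return TitrationResult(table=table, concentration=0.0,
                               ci=(0.0, _upper_at_zero(v, n)))

    def loglik(lam: float) -> float:
        p = -np.expm1(-lam * v)
        with np.errstate(divide="ignore"):
            return float(np.sum(k * np.log(p) - (n - k) * lam * v))

    def score(lam: float) -> float:
        em = np.exp(-lam * v)
        return float(np.sum(k * v * em / (1.0 - em) - (n - k) * v))

    lo, hi = 1e-12, 1.0
    while score(hi) > 0 and hi < 1e9:
        hi *= 2.0
    lam_hat = optimize.brentq(score, lo, hi)
    ll_max = loglik(lam_hat)
    cut = ll_max - stats.chi2.ppf(0.95, 1) / 2.0

    def drop(lam: float) -> float:
        return loglik(lam) - cut

    ci_lo = optimize.brentq(drop, 1e-12, lam_hat) if drop(1e-12) < 0 else 0.0
    up = lam_hat
    while drop(up * 2) > 0 and up < 1e9:
        up *= 2.0
    ci_hi = optimize.brentq(drop, lam_hat, up * 2) if up < 1e9 else np.inf
    return TitrationResult(table=table, concentration=float(lam_hat),
                           ci=(float(ci_lo), float(ci_hi)))


def _upper_at_zero(v: np.ndarray, n: np.ndarray) -> float:
    # lambda with 5% chance of zero positives across all wells
    return float(-np.log(0.05) / np.sum(n * v))


def pollen_cm(conc_crossover: float, conc_parental: float) -> float:
    """Amplicon genetic distance from crossover vs parental molecule concentrations.

    cM = 100 * c_co / (c_co + c_par).  The crossover assay amplifies one of
    the two reciprocal crossover classes and the parental assay one of the
    two parental classes, so the factors of two cancel.
    """
    if conc_crossover < 0 or conc_parental < 0:
        raise ValueError("concentrations must be >= 0")
    total = conc_crossover + conc_parental
    if total == 0:
        raise ValueError("both concentrations are zero")
    return 100.0 * conc_crossover / total


# ---------------------------------------------------------------------------
# read classification and the filter cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadEnd:
    """One read end placed by exact matching: haplotype, template coords, strand."""

    haplotype: str  # Col | Ler | ambiguous | unmapped
    start: int | None = None  # 1-based template coordinate
    end: int | None = None
    strand: str | None = None


@dataclass
class ReadPairRecord:
    """A classified read pair moving through the filter cascade."""

    pair_id: str
    end1: ReadEnd
    end2: ReadEnd
    status: str = "retained"

    @property
    def retained(self) -> bool:
        return self.status == "retained"

    def haplotype_end(self, haplotype: str) -> ReadEnd | None:
        if self.end1.haplotype == haplotype:
            return self.end1
        if self.end2.haplotype == haplotype:
            return self.end2
        return None


def _occurrences(haystack: str, needle: str, limit: int = 2) -> list[int]:
    """0-based match offsets, at most ``limit`` of them."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1 and len(out) < limit:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def classify_read(read_seq: str, template: AmpliconTemplate) -> ReadEnd:
    """Place a read by exact full-length match against both haplotypes.

    The read (or its reverse complement) must match a haplotype sequence
    exactly.  A read matching only the Col sequence is Col, only Ler is
    Ler; matching both (it covers no SNP) or matching one haplotype at more
    than one position is ``ambiguous``; matching neither (e.g. a sequencing
    error under exact matching) is ``unmapped``.
    """
    read_seq = read_seq.upper()
    if len(read_seq) > len(template):
        raise ValueError("read longer than template")
    rc = _revcomp(read_seq)
    hits: list[tuple[str, int, str]] = []  # (haplotype, offset0, strand)
    for hap, seq in (("Col", template.col_seq), ("Ler", template.ler_seq)):
        for strand, probe in (("+", read_seq), ("-", rc)):
            for off in _occurrences(seq, probe):
                hits.append((hap, off, strand))
    if not hits:
        return ReadEnd("unmapped")
    haps = {h for h, _, _ in hits}
    if len(haps) > 1 or len(hits) > 1:
        return ReadEnd("ambiguous")
    hap, off, strand = hits[0]
    return ReadEnd(hap, start=off + 1, end=off + len(read_seq), strand=strand)


def classify_pairs(pairs: Iterable, template: AmpliconTemplate) -> list[ReadPairRecord]:
    """Classify both ends of each pair.

    ``pairs`` yields objects with ``pair_id``/``seq1``/``seq2`` attributes
    (e.g. :class:`~xover.simulate.SimulatedReadPair`) or
    (pair_id, seq1, seq2) tuples.
    """
    records = []
    for p in pairs:
        if hasattr(p, "seq1"):
            pid, s1, s2 = p.pair_id, p.seq1, p.seq2
        else:
            pid, s1, s2 = p
        records.append(ReadPairRecord(pid, classify_read(s1, template),
                                      classify_read(s2, template)))
    return records


FILTER_NAMES = ("Mapped", "Unique", "Matched", "Orientate", "Strand")


def filter_crossover_pairs(records: Sequence[ReadPairRecord],
                           orientation: str = "ler-left",
                           ) -> tuple[list[ReadPairRecord], pd.DataFrame]:
    """Sequential crossover read-pair filters with per-filter attrition.

    Mapped: both ends exact-matched somewhere. Unique: neither end
    ambiguous. Matched: the two ends lie on different haplotypes.
    Orientate: the Ler end has the lower coordinate (``orientation=
    'col-left'`` flips the polarity, for amplicons read in the other genomic
    orientation). Strand: the ends map to opposite strands.  Dropped records
    get ``status='dropped_at:<filter>'``; re-running the cascade on the
    retained records is a no-op.
    """
    if orientation not in ("ler-left", "col-left"):
        raise ValueError("orientation must be 'ler-left' or 'col-left'")

    def mapped(r: ReadPairRecord) -> bool:
        return "unmapped" not in (r.end1.haplotype, r.end2.haplotype)

    def unique(r: ReadPairRecord) -> bool:
        return "ambiguous" not in (r.end1.haplotype, r.end2.haplotype)

    def matched(r: ReadPairRecord) -> bool:
        return {r.end1.haplotype, r.end2.haplotype} == {"Col", "Ler"}

    def orientate(r: ReadPairRecord) -> bool:
        ler, col = r.haplotype_end("Ler"), r.haplotype_end("Col")
        if orientation == "ler-left":
            return ler.start < col.start
        return col.start < ler.start

    def strand(r: ReadPairRecord) -> bool:
        return r.end1.strand != r.end2.strand

    preds = dict(zip(FILTER_NAMES, (mapped, unique, matched, orientate, strand)))
    current = [r for r in records if r.retained]
    rows = [("Total", len(current))]
    for name, pred in preds.items():
        nxt = []
        for r in current:
            if pred(r):
                nxt.append(r)
            else:
                r.status = f"dropped_at:{name}"
        current = nxt
        rows.append((name, len(current)))
    attrition = pd.DataFrame(rows, columns=["filter", "pairs_surviving"])
    return current, attrition


# ---------------------------------------------------------------------------
# fractional interval assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntervalProfile:
    """Per SNP-interval crossover weight profile.

    ``table`` columns: start, end (1-based SNP positions bounding each
    interval), width_bp, raw_weight, normalized_weight and, when an amplicon
    genetic distance was supplied, cm_per_mb.  Normalized weights sum to 1
    whenever ``n_pairs_used`` > 0.
    """

    table: pd.DataFrame
    n_pairs_used: int
    span_mode: str

    def __post_init__(self) -> None:
        if self.n_pairs_used > 0:
            s = float(self.table["normalized_weight"].sum())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"normalized weights sum to {s}, not 1")
        if (self.table["raw_weight"] < 0).any():
            raise ValueError("raw weights must be >= 0")


def _pair_gap(record: ReadPairRecord, snp_positions: np.ndarray,
              span_mode: str) -> tuple[int, int] | None:
    """Uncertainty region (a, b] for one retained pair, as (a, d).

    ``inner-gap``: the unsequenced interior between the two reads.
    ``snp-bounded``: shrunk to (last SNP of the lower-coordinate read, first
    SNP of the higher-coordinate read) when read-covered SNPs constrain the
    crossover more tightly.  Returns None when the region is empty
    (overlapping reads).
    """
    e1, e2 = record.end1, record.end2
    left, right = (e1, e2) if e1.start <= e2.start else (e2, e1)
    if span_mode == "inner-gap":
        a = left.end
        d = right.start - 1 - a
        if d <= 0:
            return None
        return a, d
    if span_mode == "snp-bounded":
        i = np.searchsorted(snp_positions, left.end, side="right") - 1
        j = np.searchsorted(snp_positions, right.start, side="left")
        if i < 0 or j >= snp_positions.size:
            return None
        a_snp = int(snp_positions[i])  # last SNP covered by (or before) left read
        b_snp = int(snp_positions[j])  # first SNP covered by (or after) right read
        if a_snp < left.start or b_snp > right.end:
            # fall back to the inner gap when a read covers no SNP
            a, d = left.end, right.start - 1 - left.end
            if d <= 0:
                return None
            return a, d
        d = max(b_snp - 1 - a_snp, 1)
        return a_snp, d
    raise ValueError("span_mode must be 'inner-gap' or 'snp-bounded'")


def fractional_interval_assignment(retained_pairs: Sequence[ReadPairRecord],
                                   snp_positions: Sequence[int],
                                   span_mode: str = "snp-bounded",
                                   amplicon_cm: float | None = None,
                                   ) -> IntervalProfile:
    """Distribute each pair's unit crossover weight over SNP-delimited intervals.

    For a pair with uncertainty gap of d bp, every bp in the gap receives
    1/d; a SNP-delimited sub-interval of width w inside the gap therefore
    receives w/d.  Weights are accumulated over pairs and normalized by the
    number of pairs used, so the normalized profile sums to 1.  Pairs with
    an empty gap (overlapping reads) are excluded with
    ``status='dropped_at:gap'``.
    """
    snps = np.asarray(sorted(snp_positions), dtype=np.int64)
    if snps.size < 2:
        raise ValueError("need >= 2 SNP positions")
    if len(retained_pairs) == 0:
        raise ValueError("no retained pairs")
    n_bins = snps.size - 1
    raw = np.zeros(n_bins)
    n_used = 0
    for rec in retained_pairs:
        got = _pair_gap(rec, snps, span_mode)
        if got is None:
            rec.status = "dropped_at:gap"
            continue
        a, d = got
        b = a + d
        inside = snps[(snps > a) & (snps < b)]
        edges = np.concatenate(([a], inside, [b]))
        widths = np.diff(edges)
        bins = np.searchsorted(snps, edges[:-1], side="right") - 1
        ok = (bins >= 0) & (bins < n_bins)
        np.add.at(raw, bins[ok], widths[ok] / d)
        n_used += 1
    if n_used == 0:
        raise ValueError("every pair was dropped at the gap filter")
    norm = raw / n_used
    table = pd.DataFrame({
        "start": snps[:-1],
        "end": snps[1:],
        "width_bp": np.diff(snps),
        "raw_weight": raw,
        "normalized_weight": norm,
    })
    if amplicon_cm is not None:
        table["cm_per_mb"] = amplicon_cm * norm / (table["width_bp"] / 1e6)
    return IntervalProfile(table=table, n_pairs_used=n_used, span_mode=span_mode)


# ---------------------------------------------------------------------------
# Sanger single-molecule assignment
# ---------------------------------------------------------------------------

def sanger_crossover_interval(haplotype_calls: Sequence[str],
                              snp_positions: Sequence[int]) -> tuple[int, int]:
    """Crossover interval of one Sanger-sequenced molecule.

    ``haplotype_calls`` gives 'L' (Ler) or 'C' (Col) per SNP along the
    molecule.  A crossover molecule is one haplotype for a prefix of SNPs
    and the other for the suffix; the crossover lies between the last SNP of
    one and the first SNP of the other.  Returns the 0-based (left, right)
    SNP indices bounding the interval.  More than one switch raises
    :class:`ComplexMoleculeError`.
    """
    calls = [c.upper() for c in haplotype_calls]
    snps = np.asarray(snp_positions)
    if len(calls) != snps.size:
        raise ValueError("one call per SNP required")
    if set(calls) - {"L", "C"}:
        raise ValueError("calls must be 'L' or 'C'")
    arr = np.asarray(calls)
    switch = np.flatnonzero(arr[:-1] != arr[1:])
    if switch.size == 0:
        raise ValueError("molecule is non-recombinant (no haplotype switch)")
    if switch.size > 1:
        raise ComplexMoleculeError(f"{switch.size} haplotype switches")
    j = int(switch[0])
    return j, j + 1


def aggregate_sanger(molecules: Sequence[Sequence[str]],
                     snp_positions: Sequence[int],
                     amplicon_cm: float) -> pd.DataFrame:
    """Per-interval crossover counts and cM/Mb from Sanger-typed molecules.

    Complex molecules (>1 switch) and non-recombinant molecules are excluded
    and tallied in the result's ``attrs['excluded']``.
    """
    snps = np.asarray(sorted(snp_positions), dtype=np.int64)
    counts = np.zeros(snps.size - 1, dtype=np.int64)
    excluded = {"complex": 0, "non_recombinant": 0}
    n_used = 0
    for calls in molecules:
        try:
            j, _ = sanger_crossover_interval(calls, snps)
        except ComplexMoleculeError:
            excluded["complex"] += 1
            continue
        except ValueError:
            excluded["non_recombinant"] += 1
            continue
        counts[j] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable crossover molecules")
    widths = np.diff(snps)
    out = pd.DataFrame({
        "start": snps[:-1],
        "end": snps[1:],
        "width_bp": widths,
        "count": counts,
        "cm_per_mb": amplicon_cm * (counts / n_used) / (widths / 1e6),
    })
    out.attrs["excluded"] = excluded
    out.attrs["n_molecules"] = n_used
    return out


# ---------------------------------------------------------------------------
# model wrapper
# ---------------------------------------------------------------------------

@dataclass
class CrossoverAmplicon:
    """Model: fine-scale crossover profile of one amplicon from read pairs."""

    template: AmpliconTemplate
    orientation: str = "ler-left"
    span_mode: str = "snp-bounded"

    def fit(self, pairs: Iterable, amplicon_cm: float | None = None,
            ) -> "CrossoverProfileResults":
        records = classify_pairs(pairs, self.template)
        retained, attrition = filter_crossover_pairs(records, self.orientation)
        profile = fractional_interval_assignment(
            retained, self.template.snp_positions,
            span_mode=self.span_mode, amplicon_cm=amplicon_cm)
        return CrossoverProfileResults(model=self, records=records,
                                       attrition=attrition, profile=profile,
                                       amplicon_cm=amplicon_cm)


@dataclass
class CrossoverProfileResults:
    """Classified records, filter attrition and the weighted interval profile."""

    model: CrossoverAmplicon
    records: list[ReadPairRecord] = field(repr=False, default_factory=list)
    attrition: pd.DataFrame | None = None
    profile: IntervalProfile | None = None
    amplicon_cm: float | None = None

    def summary(self) -> str:
        lines = ["Amplicon crossover read-pair profile",
                 "====================================",
                 f"span mode     {self.profile.span_mode}",
                 f"pairs in      {len(self.records)}",
                 f"pairs used    {self.profile.n_pairs_used}"]
        for _, row in self.attrition.iterrows():
            lines.append(f"  {row['filter']:<10} {row['pairs_surviving']}")
        top = self.profile.table.nlargest(3, "normalized_weight")
        for _, r in top.iterrows():
            lines.append(f"peak interval {int(r['start'])}-{int(r['end'])} "
                         f"weight {r['normalized_weight']:.4f}")
        return "\n".join(lines)

    def to_tsv(self, profile_path, attrition_path=None) -> None:
        self.profile.table.to_csv(profile_path, sep="\t", index=False)
        if attrition_path is not None:
            self.attrition.to_csv(attrition_path, sep="\t", index=False)
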