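"""Post-processing of LD-based (population-scaled) recombination maps.

Composite-likelihood LD analysis yields per-SNP-interval population-scaled
rates rho = 4Ner.  Before comparison with experimental maps these are
masked (implausibly high rho or very sparse SNP intervals are set to zero)
and rescaled to cM/Mb by ordinary least-squares regression of an
experimental genetic map on the aggregated rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RhoMap", "filter_rho_map", "rescale_to_cm"]


@dataclass(frozen=True)
class RhoMap:
    """Recombination rates per SNP interval on one scale.

    ``table`` columns: chrom, start, end (SNP positions bounding each
    interval, start < end, increasing) and ``rho`` (4Ner per bp on the
    population scale, or cM/Mb after rescaling).
    """

    table: pd.DataFrame
    scale: str = "population"  # population | cm_per_mb

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        object.__setattr__(self, "table", t)
        if self.scale not in ("population", "cm_per_mb"):
            raise ValueError("scale must be 'population' or 'cm_per_mb'")
        if (t["rho"] < 0).any():
            raise ValueError("rho must be >= 0")
        for _, sub in t.groupby("chrom"):
            pos = sub[["start", "end"]].to_numpy()
            if np.any(pos[:, 1] <= pos[:, 0]) or np.any(np.diff(sub["start"]) <= 0):
                raise ValueError("SNP interval positions must be increasing")

    @classmethod
    def from_res(cls, positions: np.ndarray, mean_rho: np.ndarray,
                 chrom: str = "chr") -> "RhoMap":
        """Build from LDhat ``res``-style output: SNP position, mean rho.

        The rho attached to SNP i is taken as the rate of the interval
        [pos_i, pos_i+1); the last SNP's value is dropped.
        """
        pos = np.asarray(positions, dtype=np.int64)
        rho = np.asarray(mean_rho, dtype=float)
        if pos.size != rho.size or pos.size < 2:
            raise ValueError("need matching position/rho arrays, >= 2 SNPs")
        return cls(pd.DataFrame({"chrom": chrom, "start": pos[:-1],
                                 "end": pos[1:], "rho": rho[:-1]}))


def filter_rho_map(rho_map: RhoMap, rho_max: float = 100.0,
                   max_span_bp: int = 50_000) -> tuple[RhoMap, int]:
    """Mask implausible intervals: rho > rho_max or SNP spacing > max_span_bp.

    Masked intervals are set to zero recombination (never dropped, keeping
    the map's interval structure).  Returns the filtered map and the number
    of intervals zeroed.  Idempotent; refuses a map already on the cM/Mb
    scale.
    """
    if rho_map.scale != "population":
        raise ValueError("filter applies to population-scaled maps only")
    t = rho_map.table.copy()
    span = t["end"] - t["start"]
    mask = (t["rho"] > rho_max) | (span > max_span_bp)
    n_zeroed = int((mask & (t["rho"] > 0)).sum())
    t.loc[mask, "rho"] = 0.0
    return RhoMap(t, scale="population"), n_zeroed


def _aggregate_to(rho: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """Length-weighted mean rho over each target interval (NaN if uncovered)."""
    out = np.full(len(target), np.nan)
    for i, (_, iv) in enumerate(target.iterrows()):
        sub = rho[(rho["chrom"] == iv["chrom"]) & (rho["end"] > iv["start"]) &
                  (rho["start"] < iv["end"])]
        if len(sub) == 0:
            continue
        w = (np.minimum(sub["end"], iv["end"]) -
             np.maximum(sub["start"], iv["start"])).to_numpy(float)
        out[i] = float(np.average(sub["rho"], weights=w))
    return out


def rescale_to_cm(rho_map: RhoMap, experimental_map: pd.DataFrame,
                  intercept: bool = True) -> tuple[RhoMap, dict]:
    """Rescale a population map to cM/Mb by regression on an experimental map.

    ``experimental_map`` needs columns (chrom, start, end, cm_per_mb) in the
    same coordinate system.  rho is aggregated onto the experimental
    intervals by length-weighted mean, experimental cM/Mb is regressed on
    aggregated rho by OLS (intercept optional), and the fitted line is
    applied to the whole map; negative rescaled values are clamped to zero.
    Returns the rescaled map and a fit-info dict (slope, intercept, r2,
    n_intervals_used, n_clamped).
    """
    if rho_map.scale != "population":
        raise ValueError("rescale applies to population-scaled maps only")
    agg = _aggregate_to(rho_map.table, experimental_map)
    ok = ~np.isnan(agg)
    if ok.sum() < 3:
        raise ValueError("need >= 3 experimental intervals overlapping the rho map")
    y = experimental_map.loc[ok, "cm_per_mb"].to_numpy(float)
    x = agg[ok]
    if np.ptp(x) == 0:
        # constant rho carries no scale information: map it to the
        # experimental mean (slope pinned at zero)
        b0, b1 = (float(y.mean()), 0.0) if intercept else (0.0, float(y.mean() / x[0]))
        r2 = 0.0
    else:
        X = sm.add_constant(x, has_constant="add") if intercept else x[:, None]
        fit = sm.OLS(y, X).fit()
        if intercept:
            b0, b1 = float(fit.params[0]), float(fit.params[1])
        else:
            b0, b1 = 0.0, float(fit.params[0])
        r2 = float(fit.rsquared)
    t = rho_map.table.copy()
    scaled = b0 + b1 * t["rho"].to_numpy(float)
    n_clamped = int((scaled < 0).sum())
    t["rho"] = np.clip(scaled, 0.0, None)
    info = {"slope": b1, "intercept": b0, "r2": r2,
            "n_intervals_used": int(ok.sum()), "n_clamped": n_clamped}
    return RhoMap(t, scale="cm_per_mb"), info
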