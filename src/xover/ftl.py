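"""Fluorescent-pollen (FTL) genetic distances and a binomial GLM on counts.

Two linked transgenes expressing pollen-autonomous fluorophores segregate
through male meiosis: pollen from a hemizygous F1 falls into four classes —
both colors or no color (parental) and yellow-alone or red-alone
(crossover).  Genetic distance is cM = 100 * Y / (Y + RY) with Y the
yellow-alone and RY the both-color count.  Genotype effects on the
recombinant fraction are tested with a logit-link binomial GLM with
genotype and replicate as fixed-effect predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "PollenSample",
    "GLMFit",
    "ftl_cm",
    "fit_binomial_glm",
    "FtlExperiment",
]


@dataclass(frozen=True)
class PollenSample:
    """Four-class pollen counts from one flow-cytometry run."""

    genotype: str
    replicate: str
    none: int
    red_only: int
    yellow_only: int
    red_and_yellow: int

    def __post_init__(self) -> None:
        counts = (self.none, self.red_only, self.yellow_only, self.red_and_yellow)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if sum(counts) == 0:
            raise ValueError("empty pollen sample")

    @property
    def total(self) -> int:
        return self.none + self.red_only + self.yellow_only + self.red_and_yellow

    def recombinant_trials(self, definition: str = "yellow-only") -> tuple[int, int]:
        """(successes, trials) entering the GLM under a recombinant definition.

        'yellow-only' mirrors the cM formula: Y out of Y + RY.
        'both-single' uses all recombinant classes: Y + R out of the total.
        """
        if definition == "yellow-only":
            return self.yellow_only, self.yellow_only + self.red_and_yellow
        if definition == "both-single":
            return self.yellow_only + self.red_only, self.total
        raise ValueError("definition must be 'yellow-only' or 'both-single'")


def ftl_cm(yellow_only: int, red_and_yellow: int) -> tuple[float, float]:
    """Genetic distance between the FTL insertions, with binomial SE.

    cM = 100 * Y / (Y + RY); the SE is the binomial standard error of the
    proportion scaled by 100.
    """
    n = yellow_only + red_and_yellow
    if n <= 0:
        raise ValueError("yellow_only + red_and_yellow must be positive")
    p = yellow_only / n
    return 100.0 * p, 100.0 * float(np.sqrt(p * (1 - p) / n))


@dataclass
class GLMFit:
    """Binomial GLM fit: per-genotype effects on the recombinant fraction.

    ``genotype_table`` rows (one per non-reference genotype): coefficient on
    the logit scale, SE, Wald z, p, significance flag, and per-genotype cM.
    ``params`` carries the full coefficient vector including replicate terms.
    """

    params: pd.Series
    bse: pd.Series
    genotype_table: pd.DataFrame
    reference: str
    converged: bool
    n_iterations: int
    alpha: float = 0.05
    separated: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Binomial GLM (logit link), reference genotype: {self.reference}",
                 f"converged: {self.converged} in {self.n_iterations} iterations", ""]
        lines.append(self.genotype_table.to_string(
            float_format=lambda v: f"{v: .4g}"))
        if self.separated:
            lines.append(f"separated genotypes (exact-test fallback): "
                         f"{', '.join(self.separated)}")
        return "\n".join(lines)


def fit_binomial_glm(samples: Sequence[PollenSample], reference_genotype: str,
                     recombinant_definition: str = "yellow-only",
                     alpha: float = 0.05) -> GLMFit:
    """Fit recombinant counts ~ genotype + replicate, binomial with logit link.

    Genotype and replicate enter as fixed-effect indicator variables
    (treatment coding, ``reference_genotype`` as the genotype baseline).
    Each genotype's Wald z/p tests its logit-scale shift against the
    reference.  A genotype with zero or all recombinants separates the
    likelihood; its coefficient is reported as +/-inf and its p-value falls
    back to Fisher's exact test of its pooled counts against the
    reference's.
    """
    genotypes = sorted({s.genotype for s in samples})
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes")
    if reference_genotype not in genotypes:
        raise ValueError(f"reference genotype {reference_genotype!r} absent")
    rows = []
    for s in samples:
        succ, n = s.recombinant_trials(recombinant_definition)
        rows.append((s.genotype, s.replicate, succ, n))
    df = pd.DataFrame(rows, columns=["genotype", "replicate", "success", "n"])
    if (df["n"] == 0).any():
        raise ValueError("a sample has zero trials under this recombinant definition")

    pooled = df.groupby("genotype")[["success", "n"]].sum()
    separated = [g for g, r in pooled.iterrows()
                 if r["success"] == 0 or r["success"] == r["n"]]

    others = [g for g in genotypes if g != reference_genotype]
    reps = sorted(df["replicate"].unique())
    X = pd.DataFrame({"const": np.ones(len(df))})
    for g in others:
        X[f"genotype[{g}]"] = (df["genotype"] == g).astype(float)
    for r in reps[1:]:
        X[f"replicate[{r}]"] = (df["replicate"] == r).astype(float)
    endog = df[["success"]].copy()
    endog["failure"] = df["n"] - df["success"]

    model = sm.GLM(endog.to_numpy(float), X.to_numpy(float),
                   family=sm.families.Binomial())
    # saturated or separated data makes IRLS warn about perfect prediction;
    # separated genotypes are handled explicitly below, saturated designs
    # (one observation per cell) are legitimate
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(tol=1e-10, maxiter=50)
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    n_iter = len(res.fit_history.get("deviance", [0])) - 1

    ref_succ, ref_n = pooled.loc[reference_genotype]
    table_rows = []
    for g in others:
        name = f"genotype[{g}]"
        coef, se = params[name], bse[name]
        succ, n = pooled.loc[g]
        if g in separated or reference_genotype in separated:
            sign = 1.0 if succ / n > ref_succ / ref_n else -1.0
            coef = sign * np.inf if g in separated else coef
            se = np.nan
            tab = [[int(succ), int(n - succ)], [int(ref_succ), int(ref_n - ref_succ)]]
            p = float(stats.fisher_exact(tab)[1])
            z = np.nan
        else:
            z = coef / se
            p = 2.0 * float(stats.norm.sf(abs(z)))
        table_rows.append((g, coef, se, z, p, p < alpha, 100.0 * succ / n))
    table = pd.DataFrame(table_rows, columns=["genotype", "coef", "se", "z", "p",
                                              "significant", "cm"])
    table.insert(6, "reference_cm", 100.0 * ref_succ / ref_n)
    return GLMFit(params=params, bse=bse, genotype_table=table,
                  reference=reference_genotype, converged=bool(res.converged),
                  n_iterations=max(n_iter, 1), alpha=alpha, separated=separated)


@dataclass
class FtlExperiment:
    """Model wrapper: per-genotype cM plus the genotype-effect GLM."""

    samples: list[PollenSample]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FtlExperiment":
        """Build from a table with columns genotype, replicate, n_none, n_red,
        n_yellow, n_red_yellow."""
        samples = [PollenSample(str(r["genotype"]), str(r["replicate"]),
                                int(r["n_none"]), int(r["n_red"]),
                                int(r["n_yellow"]), int(r["n_red_yellow"]))
                   for _, r in df.iterrows()]
        return cls(samples)

    def cm_table(self) -> pd.DataFrame:
        """Per-sample and per-genotype genetic distances with SEs."""
        rows = []
        for s in self.samples:
            cm, se = ftl_cm(s.yellow_only, s.red_and_yellow)
            rows.append((s.genotype, s.replicate, s.total, cm, se))
        return pd.DataFrame(rows, columns=["genotype", "replicate", "total_pollen",
                                           "cm", "se"])

    def fit(self, reference_genotype: str,
            recombinant_definition: str = "yellow-only",
            alpha: float = 0.05) -> GLMFit:
        return fit_binomial_glm(self.samples, reference_genotype,
                                recombinant_definition, alpha)
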