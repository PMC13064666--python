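"""Frequency dynamics and the statistical layer.

Baseline-relative frequency shifts of shared mutations (3-month mean as the
baseline, all sites pooled), fixed-effects ANOVA with sequential sums of
squares (exact on balanced layouts, documented sequential fitting
otherwise), Tukey's HSD from the studentized-range distribution, and
per-variant Pearson correlations with site abiotic covariates. No
multiple-testing correction is applied across variants by default; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .census import MutationMatrix


@dataclass
class FreqShift:
    variant: tuple
    sample_id: str
    delta: float          # percentage points vs the baseline mean
    baseline_missing: bool = False

    def __post_init__(self):
        if not -100.0 <= self.delta <= 100.0:
            raise ValueError("delta outside [-100, 100] percentage points")


def baseline_shift(matrix: MutationMatrix, target_timepoint: int,
                   baseline_timepoint: int = 3) -> list[FreqShift]:
    """Per-sample frequency change vs the pooled baseline mean.

    The baseline for each variant is its mean frequency across *all*
    baseline-timepoint samples (sites pooled); deltas are in percentage
    points. A variant never detected at baseline gets baseline 0 and is
    flagged.
    """
    samples = matrix.samples
    base_cols = samples.index[samples["timepoint"] == baseline_timepoint]
    tgt_cols = samples.index[samples["timepoint"] == target_timepoint]
    if len(base_cols) == 0:
        raise ValueError(f"no samples at baseline timepoint {baseline_timepoint}")

    base_mean = matrix.frequencies[base_cols].mean(axis=1)
    base_detected = matrix.detected[base_cols].any(axis=1)
    shifts = []
    for key in matrix.frequencies.index:
        b = float(base_mean.loc[key])
        missing = not bool(base_detected.loc[key])
        if missing:
            b = 0.0
        for sid in tgt_cols:
            f = float(matrix.frequencies.loc[key, sid])
            shifts.append(FreqShift(variant=key, sample_id=sid,
                                    delta=100.0 * (f - b),
                                    baseline_missing=missing))
    return shifts


def shifts_to_frame(shifts: list[FreqShift]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variant": s.variant, "sample_id": s.sample_id, "delta": s.delta,
          "baseline_missing": s.baseline_missing} for s in shifts])


@dataclass
class AnovaTable:
    """Fixed-effects decomposition: one row per term plus the residual."""

    table: pd.DataFrame    # index term; columns sum_sq, df, mean_sq, F, p

    @property
    def terms(self):
        return [t for t in self.table.index if t != "Residual"]

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def residual_ms(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    def residual_df(self) -> float:
        return float(self.table.loc["Residual", "df"])


def anova(data: pd.DataFrame, response: str, factors: list[str],
          interaction: bool = True) -> AnovaTable:
    """One- or two-way fixed-effects ANOVA with sequential (type I) sums of
    squares via an OLS fit.

    Two factors include their interaction by default. Degenerate inputs:
    all-equal responses yield zero SS and NaN F (flagged, not an error);
    zero residual degrees of freedom raise.
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("anova supports 1 or 2 factors")
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    if len(data) < 2:
        raise ValueError("need >= 2 observations")

    rhs = " * ".join(f"C({f})" for f in factors)
    if len(factors) == 2 and not interaction:
        rhs = " + ".join(f"C({f})" for f in factors)
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    with np.errstate(invalid="ignore", divide="ignore"):
        raw = anova_lm(model, typ=1)
    tbl = raw.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    tbl["mean_sq"] = tbl["sum_sq"] / tbl["df"]
    # readable term names: C(site) -> site, C(a):C(b) -> a:b
    tbl.index = [t.replace("C(", "").replace(")", "") for t in tbl.index]
    if np.ptp(data[response].to_numpy(float)) == 0:
        # all observations equal: the decomposition is all zeros and the
        # F ratio is undefined, flagged as NaN rather than raised
        terms = tbl.index != "Residual"
        tbl.loc[:, "sum_sq"] = 0.0
        tbl.loc[:, "mean_sq"] = 0.0
        tbl.loc[terms, ["F", "p"]] = np.nan
    return AnovaTable(table=tbl[["sum_sq", "df", "mean_sq", "F", "p"]])


@dataclass
class TukeyResult:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p: float

    def __post_init__(self):
        if not (math.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")


def tukey_hsd(group_means: dict, residual_ms: float, residual_df: float,
              group_sizes: dict) -> list[TukeyResult]:
    """Tukey's HSD from precomputed group means and the ANOVA residual.

    q = |mean_i - mean_j| / sqrt(MS_res/2 * (1/n_i + 1/n_j)); adjusted p
    from the studentized-range distribution with (k, residual df).
    """
    groups = sorted(group_means)
    k = len(groups)
    if k < 2:
        raise ValueError("Tukey's HSD needs >= 2 groups")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = group_means[a] - group_means[b]
            se = math.sqrt(residual_ms / 2.0
                           * (1.0 / group_sizes[a] + 1.0 / group_sizes[b]))
            if se == 0:
                q = 0.0 if diff == 0 else math.inf
            else:
                q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, residual_df))
            out.append(TukeyResult(a, b, diff, q, p))
    return out


def tukey_from_groups(data: pd.DataFrame, response: str,
                      factor: str) -> list[TukeyResult]:
    """Convenience: one-way ANOVA on ``factor`` followed by Tukey's HSD."""
    table = anova(data, response, [factor])
    means = data.groupby(factor)[response].mean().to_dict()
    sizes = data.groupby(factor)[response].size().to_dict()
    return tukey_hsd(means, table.residual_ms(), table.residual_df(), sizes)


@dataclass
class CorrelationResult:
    variant: tuple
    covariate: str
    r: float
    p: float
    flagged: bool = False   # zero variance in either vector

    def __post_init__(self):
        if not (math.isnan(self.r) or -1.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r outside [-1, 1]")


def abiotic_correlation(matrix: MutationMatrix, covariates: pd.DataFrame,
                        timepoint: int) -> list[CorrelationResult]:
    """Pearson correlation between per-sample variant frequency and the
    sample's site covariate at one timepoint; two-sided p via the t
    transform. Covariates: DataFrame indexed by site."""
    samples = matrix.samples[matrix.samples["timepoint"] == timepoint]
    if samples["site"].nunique() < 3:
        raise ValueError("abiotic correlation needs >= 3 sites")
    cols = samples.index
    out = []
    for cov in covariates.columns:
        x = samples["site"].map(covariates[cov]).to_numpy(float)
        for key in matrix.frequencies.index:
            y = matrix.frequencies.loc[key, cols].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out.append(CorrelationResult(key, cov, math.nan, math.nan,
                                             flagged=True))
                continue
            r, p = stats.pearsonr(x, y)
            out.append(CorrelationResult(key, cov, float(r), float(p)))
    return out


def correlations_to_frame(results: list[CorrelationResult],
                          bh_adjust: bool = False) -> pd.DataFrame:
    """Tabulate correlation results; optional Benjamini-Hochberg adjusted
    q-values across all non-flagged tests (off by default)."""
    df = pd.DataFrame([{"variant": r.variant, "covariate": r.covariate,
                        "r": r.r, "p": r.p, "flagged": r.flagged}
                       for r in results])
    if bh_adjust and len(df):
        ok = ~df["flagged"]
        q = np.full(len(df), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(df.loc[ok, "p"],
                                             method="fdr_bh")[1]
        df["q_bh"] = q
    return df
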