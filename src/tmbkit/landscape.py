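"""Cohort-level summaries: eligibility, per-disease TMB, age trend, MSI x TMB.

High TMB is strictly more than 20 mutations/Mb; the MSI comparison
additionally uses a >= 10 mutations/Mb cut.  Percentages are displayed with
half-away-from-zero rounding; binomial confidence intervals use the Wilson
score method by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

HIGH_TMB_THRESHOLD = 20.0
MSI_TMB_THRESHOLD = 10.0
MIN_COVERAGE = 300.0
MIN_DISEASE_N = 50


class LandscapeError(ValueError):
    pass


def tally_percent(k: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*k/n rounded half-away-from-zero to ``decimals`` places."""
    if n < 1 or k < 0 or k > n:
        raise LandscapeError(f"invalid tally k={k}, n={n}")
    pct = Decimal(100 * k) / Decimal(n)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def binomial_ci(k: int, n: int, level: float = 0.95,
                method: str = "wilson") -> tuple[float, float]:
    """Binomial proportion CI in percent units.

    Wilson score by default; ``method='exact'`` gives Clopper-Pearson.
    ``level >= 1`` degenerates to the full [0, 100] interval.
    """
    if not 0 <= k <= n or n < 1:
        raise LandscapeError(f"invalid counts k={k}, n={n}")
    if level >= 1.0:
        return 0.0, 100.0
    if method == "exact":
        alpha = 1 - level
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
        return 100.0 * lo, 100.0 * hi
    if method != "wilson":
        raise LandscapeError(f"unknown CI method {method!r}")
    z = stats.norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)  # analytic boundary exact
    return 100.0 * lo, 100.0 * hi


def filter_cohort(specimens: pd.DataFrame,
                  min_coverage: float = MIN_COVERAGE
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Eligibility filter: one specimen per patient, then coverage >= 300x.

    Duplicates resolve to the first specimen in stable input order.  Returns
    the eligible frame plus exclusion counts by reason.  Idempotent.
    """
    if len(specimens) == 0:
        return specimens.copy(), {"duplicate_patient": 0, "low_coverage": 0}
    deduped = specimens.drop_duplicates(subset="patient_id", keep="first")
    n_dupes = len(specimens) - len(deduped)
    eligible = deduped[deduped["median_coverage"] >= min_coverage]
    n_low = len(deduped) - len(eligible)
    return eligible.reset_index(drop=True), {
        "duplicate_patient": int(n_dupes),
        "low_coverage": int(n_low),
    }


def disease_summary(specimens: pd.DataFrame,
                    high_threshold: float = HIGH_TMB_THRESHOLD,
                    min_n: int = MIN_DISEASE_N,
                    ci_level: float = 0.95) -> pd.DataFrame:
    """Per-disease TMB distribution for diseases with at least ``min_n`` cases.

    Columns: disease, n, median_tmb, q25, q75, pct_high (strictly above the
    threshold), ci_low, ci_high.  Sorted by pct_high descending.
    """
    if specimens["tmb"].isna().any():
        raise LandscapeError("tmb missing for some specimens")
    rows = []
    for disease, grp in specimens.groupby("disease"):
        n = len(grp)
        if n < min_n:
            continue
        tmb = grp["tmb"].to_numpy(dtype=float)
        k = int((tmb > high_threshold).sum())
        lo, hi = binomial_ci(k, n, level=ci_level)
        rows.append(
            {
                "disease": disease,
                "n": n,
                "median_tmb": float(np.median(tmb)),
                "q25": float(np.percentile(tmb, 25)),
                "q75": float(np.percentile(tmb, 75)),
                "pct_high": 100.0 * k / n,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    out = pd.DataFrame(
        rows, columns=["disease", "n", "median_tmb", "q25", "q75",
                       "pct_high", "ci_low", "ci_high"]
    )
    return out.sort_values("pct_high", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class AgeTrend:
    slope_per_year: float  # in log10(TMB) units
    intercept: float
    p_value: float
    fold_10_90: float

    def fold(self, age_from: float, age_to: float) -> float:
        return float(10 ** (self.slope_per_year * (age_to - age_from)))


def age_trend(specimens: pd.DataFrame, pseudo_count: float = 1.0) -> AgeTrend:
    """Least-squares fit of log10(TMB + pseudo-count) on age.

    Reports the per-year slope and the implied fold-change between ages 10
    and 90: 10**(slope * 80).
    """
    age = specimens["age"].to_numpy(dtype=float)
    if len(np.unique(age)) < 2:
        raise LandscapeError("age_trend requires >= 2 distinct ages")
    y = np.log10(specimens["tmb"].to_numpy(dtype=float) + pseudo_count)
    fit = stats.linregress(age, y)
    return AgeTrend(
        slope_per_year=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        fold_10_90=float(10 ** (fit.slope * 80)),
    )


@dataclass
class MSITmbCrosstab:
    p_high_given_msih: float  # P(TMB > 20 | MSI-H); nan if undefined
    p_ge10_given_msih: float  # P(TMB >= 10 | MSI-H)
    p_msih_given_high: float  # P(MSI-H | TMB > 20)
    n_msih: int
    n_high: int
    defined: bool
    by_disease: pd.DataFrame


def msi_tmb_crosstab(specimens: pd.DataFrame,
                     high_threshold: float = HIGH_TMB_THRESHOLD,
                     msi_threshold: float = MSI_TMB_THRESHOLD) -> MSITmbCrosstab:
    """Cross-tabulate MSI calls against TMB cuts (cohort and per disease).

    Conditionals with an empty conditioning set are reported as NaN with
    ``defined=False`` rather than 0.
    """
    if "msi_call" not in specimens.columns:
        raise LandscapeError("specimens must carry an msi_call column")
    msih = specimens["msi_call"] == "MSI-H"
    high = specimens["tmb"] > high_threshold
    ge10 = specimens["tmb"] >= msi_threshold
    n_msih, n_high = int(msih.sum()), int(high.sum())
    p1 = float((msih & high).sum() / n_msih) if n_msih else float("nan")
    p2 = float((msih & ge10).sum() / n_msih) if n_msih else float("nan")
    p3 = float((msih & high).sum() / n_high) if n_high else float("nan")
    rows = []
    for disease, grp in specimens.groupby("disease"):
        g_msih = grp["msi_call"] == "MSI-H"
        g_high = grp["tmb"] > high_threshold
        n = len(grp)
        rows.append(
            {
                "disease": disease,
                "n": n,
                "frac_msih_and_high": float((g_msih & g_high).sum() / n),
                "frac_high_only": float((g_high & ~g_msih).sum() / n),
                "frac_msih_only": float((g_msih & ~g_high).sum() / n),
            }
        )
    return MSITmbCrosstab(
        p_high_given_msih=p1,
        p_ge10_given_msih=p2,
        p_msih_given_high=p3,
        n_msih=n_msih,
        n_high=n_high,
        defined=n_msih > 0,
        by_disease=pd.DataFrame(rows),
    )


@dataclass
class ExplainedFraction:
    k: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    defined: bool


def explained_fraction(specimens: pd.DataFrame,
                       driver_cols: list[str],
                       high_threshold: float = HIGH_TMB_THRESHOLD
                       ) -> ExplainedFraction:
    """Fraction of high-TMB specimens carrying any of the listed driver flags."""
    for col in driver_cols:
        if col not in specimens.columns:
            raise LandscapeError(f"missing driver column {col!r}")
    high = specimens[specimens["tmb"] > high_threshold]
    n = len(high)
    if n == 0:
        return ExplainedFraction(0, 0, float("nan"), float("nan"),
                                 float("nan"), False)
    any_driver = high[driver_cols].astype(bool).any(axis=1)
    k = int(any_driver.sum())
    lo, hi = binomial_ci(k, n)
    return ExplainedFraction(k, n, tally_percent(k, n, 1), lo, hi, True)
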