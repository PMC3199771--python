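"""Tip-contrast computation and sister-pair statistics.

The standardized tip contrast for a trait X between sister species 1 and 2 is

    c = (X1 - X2) / sqrt(bl1 + bl2)

with bl the branch lengths leading to each tip (taken from the phylogeny
before ultrametric correction, so the denominator is in substitutions/site).
Under Brownian motion with rate sigma^2 these contrasts have variance
sigma^2, which is what the calibration tests check.

The module also houses every pairwise test run on the contrast table:
age-range correlation, the sign test of sister vs non-sister overlap,
regressions through the origin (uncentered sums of squares), the factorial
regression with interaction terms, quantile regression (pinball-loss linear
program) for the peripatric-speciation prediction, and a one-sample
Kolmogorov-Smirnov normality check for node ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .range_geometry import RangeSet, overlap_pct
from .sister_pairs import SisterPair

__all__ = [
    "standardized_contrast",
    "build_contrast_table",
    "age_range_correlation",
    "sign_test_overlap",
    "RegressionResult",
    "regression_through_origin",
    "factorial_regression",
    "quantile_regression",
    "ks_normality",
]


def standardized_contrast(x1: float, x2: float, bl1: float, bl2: float) -> float:
    """(x1 - x2) / sqrt(bl1 + bl2); sign follows the input order."""
    denom = bl1 + bl2
    if denom <= 0:
        raise ValueError("summed branch length must be positive")
    return (x1 - x2) / math.sqrt(denom)


def build_contrast_table(
    pairs: Sequence[SisterPair],
    traits: pd.DataFrame,
    range_sets: dict[str, RangeSet],
    centroid_distances: pd.DataFrame | None = None,
    climatic_distances: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per included pair: contrasts of SVL and each range policy,
    plus covariates (age, centroid distance, climatic distance, overlap).

    Species within a pair are ordered lexicographically (species_a < species_b)
    so signed contrasts are reproducible; headline analyses use the absolute
    columns, which are order-invariant.
    """
    svl = traits.set_index("species")["svl_mm"]
    rows = []
    for p in pairs:
        if p.excluded:
            continue
        a, b = p.species_a, p.species_b
        row = {
            "species_a": a,
            "species_b": b,
            "age_ma": p.age,
            "c_svl": standardized_contrast(svl[a], svl[b], p.bl_a, p.bl_b),
        }
        for policy, rset in range_sets.items():
            ra, rb = rset[a], rset[b]
            row[f"c_{policy.lower()}"] = standardized_contrast(
                ra.area_km2, rb.area_km2, p.bl_a, p.bl_b
            )
            row[f"overlap_pct_{policy.lower()}"] = overlap_pct(ra, rb)
            row[f"area_{policy.lower()}_a"] = ra.area_km2
            row[f"area_{policy.lower()}_b"] = rb.area_km2
        if centroid_distances is not None:
            row["centroid_distance_km"] = float(centroid_distances.loc[a, b])
        if climatic_distances is not None:
            row["climatic_distance"] = float(climatic_distances.loc[a, b])
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in list(df.columns):
        if col.startswith("c_"):
            df["abs_" + col] = df[col].abs()
    return df


def age_range_correlation(
    ages: np.ndarray, overlaps: np.ndarray, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of sister-pair node age with range overlap, plus its p.

    Zero overlap-age correlation is the classic null; the sign and strength
    are read as a (coarse) signal of geographic speciation mode.
    """
    ages = np.asarray(ages, float)
    overlaps = np.asarray(overlaps, float)
    if ages.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(ages) == 0 or np.ptp(overlaps) == 0:
        raise ValueError("zero variance in age or overlap")
    if method == "pearson":
        r, p = stats.pearsonr(ages, overlaps)
    elif method == "spearman":
        r, p = stats.spearmanr(ages, overlaps)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def sign_test_overlap(
    sister_overlaps: np.ndarray,
    nonsister_overlaps: np.ndarray,
    reference: str = "median",
    normal_approx_min_n: int = 25,
) -> tuple[float, float]:
    """Sign test of sister-pair overlaps against the non-sister background.

    Each sister overlap is compared with a central value of the non-sister
    overlap distribution (median by default, mean via ``reference``); ties are
    dropped.  With n non-tied comparisons and k above the reference, the
    continuity-corrected normal approximation is

        Z = (|k - n/2| - 0.5) / (sqrt(n)/2)

    used for n >= ``normal_approx_min_n``; the exact two-sided binomial p is
    used below that.  Returns ``(Z, p)``.
    """
    sister = np.asarray(sister_overlaps, float)
    nonsister = np.asarray(nonsister_overlaps, float)
    if sister.size == 0 or nonsister.size == 0:
        raise ValueError("both overlap sets must be non-empty")
    ref = float(np.median(nonsister) if reference == "median" else np.mean(nonsister))
    diffs = sister - ref
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("all sister overlaps tie with the reference value")
    k = int(np.sum(diffs > 0))
    z = (abs(k - n / 2.0) - 0.5) / (math.sqrt(n) / 2.0)
    if n < normal_approx_min_n:
        p = stats.binomtest(k, n, 0.5).pvalue
    else:
        p = 2.0 * stats.norm.sf(z)
    return float(z), float(min(p, 1.0))


def nonsister_overlap_values(
    overlap: pd.DataFrame, sister_pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Upper-triangle overlap values for all non-sister species combinations."""
    sisters = {frozenset(p) for p in sister_pairs}
    species = list(overlap.index)
    vals = [
        overlap.loc[a, b]
        for a, b in combinations(species, 2)
        if frozenset((a, b)) not in sisters
    ]
    return np.asarray(vals, float)


@dataclass
class RegressionResult:
    """Through-origin regression summary mirroring the classic ANOVA columns."""

    params: pd.Series
    bse: pd.Series
    r2: float
    ss_model: float
    ms_model: float
    ss_residual: float
    ms_residual: float
    F: float
    p: float
    n: int
    through_origin: bool = True
    term_ss: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "multiple_r2": [self.r2],
                "ss_model": [self.ss_model],
                "ms_model": [self.ms_model],
                "ss_residual": [self.ss_residual],
                "ms_residual": [self.ms_residual],
                "F": [self.F],
                "p": [self.p],
                "n": [self.n],
            }
        )


def regression_through_origin(y, X) -> RegressionResult:
    """Least-squares fit with no intercept; R² on uncentered sums of squares.

    ``SS_total = y'y`` is decomposed into model and residual parts;
    ``F = MS_model / MS_residual`` on (p, n - p) degrees of freedom.  This is
    the convention the comparative-methods literature uses for contrast
    regressions, where the origin is forced by construction.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(X.to_numpy(float)) < k:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    ss_total = float(y @ y)
    ss_resid = float(fit.resid @ fit.resid)
    ss_model = ss_total - ss_resid
    ms_model = ss_model / k
    ms_resid = ss_resid / (n - k)
    if ms_resid > 0:
        F = ms_model / ms_resid
        p = float(stats.f.sf(F, k, n - k))
    elif ss_model > 0:  # perfect fit
        F, p = math.inf, 0.0
    else:  # y identically zero: no signal at all
        F, p = 0.0, 1.0
    # Sequential (type I) per-term SS via incremental projection.
    term_ss = {}
    prev = 0.0
    for j in range(1, k + 1):
        sub = sm.OLS(y, X.iloc[:, :j]).fit()
        explained = ss_total - float(sub.resid @ sub.resid)
        term_ss[X.columns[j - 1]] = explained - prev
        prev = explained
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        r2=0.0 if ss_total == 0 else ss_model / ss_total,
        ss_model=ss_model,
        ms_model=ms_model,
        ss_residual=ss_resid,
        ms_residual=ms_resid,
        F=F,
        p=p,
        n=n,
        term_ss=pd.Series(term_ss),
    )


def factorial_design(
    age: np.ndarray, centroid_distance: np.ndarray, climatic_distance: np.ndarray
) -> pd.DataFrame:
    """Design matrix with the three main effects, all pairwise interactions and
    the three-way interaction (no intercept)."""
    a = np.asarray(age, float)
    d = np.asarray(centroid_distance, float)
    c = np.asarray(climatic_distance, float)
    return pd.DataFrame(
        {
            "age": a,
            "dist": d,
            "clim": c,
            "age:dist": a * d,
            "age:clim": a * c,
            "dist:clim": d * c,
            "age:dist:clim": a * d * c,
        }
    )


def factorial_regression(
    y, age, centroid_distance, climatic_distance
) -> RegressionResult:
    """Through-origin factorial regression of a contrast on evolutionary age,
    range proximity (centroid distance) and bioclimatic distance, with all
    interaction terms."""
    X = factorial_design(age, centroid_distance, climatic_distance)
    return regression_through_origin(y, X)


def quantile_regression(y, x, tau: float = 0.9) -> tuple[float, float]:
    """Fit the tau-th regression quantile of y on x; returns (slope, intercept).

    Minimises the pinball loss sum rho_tau(y - a - b x) as a linear program
    (HiGHS).  The tau = 0.9 line sits above ~90% of the data; a positive
    high-quantile slope of range-size difference on age is the signature that
    speaks against peripatric speciation, which predicts large asymmetry at
    young ages (a flat or negative envelope).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x equal")
    # Variables: a+, a-, b+, b-, u (n), v (n) — all >= 0;
    # y = (a+ - a-) + (b+ - b-) x + u - v.
    c = np.concatenate([[0, 0, 0, 0], np.full(n, tau), np.full(n, 1 - tau)])
    A = np.zeros((n, 4 + 2 * n))
    A[:, 0] = 1.0
    A[:, 1] = -1.0
    A[:, 2] = x
    A[:, 3] = -x
    A[:, 4:4 + n] = np.eye(n)
    A[:, 4 + n:] = -np.eye(n)
    res = optimize.linprog(c, A_eq=A, b_eq=y, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(b), float(a)


def ks_normality(values, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of *values* against a fitted normal.

    With mean and SD estimated from the sample the standard KS p-value is
    conservative-approximate; pass ``lilliefors=True`` for the corrected
    p-value.  Returns ``(D, p)``.
    """
    v = np.asarray(values, float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        d, p = _lf(v, dist="norm")
        return float(d), float(p)
    d, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(d), float(p)
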