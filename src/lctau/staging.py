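"""Ex vivo tangle staging: cutoff derivation, concordance classes, exact
binomial proportions, Welch pairwise contrasts and partial Spearman
correlations.

The staging logic positions LC tangle pathology relative to an allocortical
region: a subject is called "high" in a region when its tangle density
strictly exceeds that region's derived mean cutoff (ties go to "low").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    StagingError,
    UndefinedCorrelationError,
)

__all__ = [
    "StagingThresholds",
    "StagingResult",
    "CLASS_LABELS",
    "derive_thresholds",
    "classify_concordance",
    "binomial_ci",
    "welch_pairwise",
    "partial_spearman",
]

CLASS_LABELS = ("low_low", "lc_only", "region_only", "both")

LC_DENSITY_COL = "lc_tangle_density"


@dataclass
class StagingThresholds:
    region: str
    lc_max_at_braak0: float
    lc_cutoff_mean: float
    lc_cutoff_ci: tuple[float, float]
    region_max_at_prior_stage: float
    region_cutoff_mean: float
    region_cutoff_ci: tuple[float, float]
    n_used: dict = field(default_factory=dict)


@dataclass
class StagingResult:
    region: str
    classes: pd.Series          # per-subject class label
    counts: dict
    proportions: dict           # class -> (p_hat, ci_low, ci_high)
    n: int
    thresholds: StagingThresholds | None = None


def _mean_t_ci(values: np.ndarray,
               alpha: float = 0.05) -> tuple[float, float, float]:
    n = values.size
    mean = float(values.mean())
    if n < 2:
        raise StagingError("need >= 2 values for a t-interval")
    se = values.std(ddof=1) / np.sqrt(n)
    half = float(stats.t.ppf(1 - alpha / 2, n - 1) * se)
    return mean, mean - half, mean + half


def derive_thresholds(records: pd.DataFrame, region: str,
                      lc_conditioning_stage: int = 0,
                      region_conditioning_stage: int = 2,
                      alpha: float = 0.05) -> StagingThresholds:
    """Two-step Braak-conditioned cutoffs for LC and one allocortical region.

    Step 1 takes the maximum density among subjects at or below the
    conditioning Braak stage (stage 0 for the LC; one stage below the stage
    of interest for the region). Step 2 takes the mean and t-based 95% CI
    of density among cognitively unimpaired subjects strictly below that
    maximum; the mean is the operating classification cutoff.
    """
    for col in (LC_DENSITY_COL, region, "braak", "group"):
        if col not in records.columns:
            raise StagingError(f"records lack required column {col!r}")

    n_used: dict[str, int] = {}

    def _two_step(col: str, stage: int, label: str) -> tuple[float, float,
                                                             tuple]:
        cond = records[(records["braak"] <= stage) & records[col].notna()]
        if cond.empty:
            raise StagingError(
                f"no subjects at Braak <= {stage} for {label} step 1",
                step=f"{label}_max",
            )
        vmax = float(cond[col].max())
        n_used[f"{label}_max"] = len(cond)
        sub = records[(records["group"] == "unimpaired")
                      & (records[col] < vmax) & records[col].notna()]
        if len(sub) < 2:
            raise StagingError(
                f"fewer than 2 unimpaired subjects below the {label} max",
                step=f"{label}_mean",
            )
        mean, lo, hi = _mean_t_ci(sub[col].to_numpy(dtype=float), alpha)
        n_used[f"{label}_mean"] = len(sub)
        return vmax, mean, (lo, hi)

    lc_max, lc_mean, lc_ci = _two_step(LC_DENSITY_COL,
                                       lc_conditioning_stage, "lc")
    rg_max, rg_mean, rg_ci = _two_step(region,
                                       region_conditioning_stage, "region")
    return StagingThresholds(
        region=region,
        lc_max_at_braak0=lc_max, lc_cutoff_mean=lc_mean, lc_cutoff_ci=lc_ci,
        region_max_at_prior_stage=rg_max, region_cutoff_mean=rg_mean,
        region_cutoff_ci=rg_ci, n_used=n_used,
    )


def classify_concordance(records: pd.DataFrame,
                         thresholds: StagingThresholds,
                         alpha: float = 0.05,
                         lc_threshold: float | None = None,
                         region_threshold: float | None = None,
                         ) -> StagingResult:
    """Four-class concordance tally with exact binomial CIs per class.

    "High" means strictly greater than the cutoff; subjects exactly at a
    cutoff are classed low for that region. ``lc_threshold`` /
    ``region_threshold`` override the mean cutoffs (e.g. to rerun at a CI
    bound). Subjects with a missing density are left unclassified.
    """
    region = thresholds.region
    lc_cut = (thresholds.lc_cutoff_mean if lc_threshold is None
              else lc_threshold)
    rg_cut = (thresholds.region_cutoff_mean if region_threshold is None
              else region_threshold)
    ok = records[LC_DENSITY_COL].notna() & records[region].notna()
    lc_high = records[LC_DENSITY_COL] > lc_cut
    rg_high = records[region] > rg_cut
    labels = pd.Series(pd.NA, index=records.index, dtype="object")
    labels[ok & ~lc_high & ~rg_high] = "low_low"
    labels[ok & lc_high & ~rg_high] = "lc_only"
    labels[ok & ~lc_high & rg_high] = "region_only"
    labels[ok & lc_high & rg_high] = "both"
    n = int(ok.sum())
    counts = {c: int((labels == c).sum()) for c in CLASS_LABELS}
    proportions = {}
    for c in CLASS_LABELS:
        p_hat, lo, hi, _ = binomial_ci(counts[c], n, alpha)
        proportions[c] = (p_hat, lo, hi)
    return StagingResult(region=region, classes=labels, counts=counts,
                         proportions=proportions, n=n,
                         thresholds=thresholds)


def binomial_ci(x: int, n: int, alpha: float = 0.05
                ) -> tuple[float, float, float, float]:
    """Clopper-Pearson exact interval and exact test against p = 1/2.

    Returns ``(p_hat, ci_low, ci_high, p_value_vs_half)``; the bounds are
    the beta-quantile form of the inverted binomial tails, with the
    conventional 0 and 1 at the x = 0 and x = n boundaries.
    """
    x, n = int(x), int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    p_hat = x / n
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    p_half = float(stats.binomtest(x, n, 0.5).pvalue)
    return p_hat, lo, hi, p_half


def welch_pairwise(groups, values, alpha: float = 0.05) -> pd.DataFrame:
    """Welch's t with Satterthwaite df for every pair of group labels.

    Returns a table with one row per pair: t, df, mean difference, CI and
    two-tailed p. Pairs where either group has fewer than 2 observations
    are skipped.
    """
    groups = pd.Series(list(groups))
    values = pd.Series(np.asarray(values, dtype=float))
    ok = groups.notna() & values.notna()
    groups, values = groups[ok], values[ok]
    rows = []
    for g1, g2 in combinations(pd.unique(groups), 2):
        a = values[groups == g1].to_numpy()
        b = values[groups == g2].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        se = np.sqrt(va + vb)
        diff = a.mean() - b.mean()
        if se == 0:
            t_stat, df, p, half = 0.0, float(len(a) + len(b) - 2), 1.0, 0.0
        else:
            t_stat = diff / se
            df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                   + vb ** 2 / (len(b) - 1))
            p = 2 * stats.t.sf(abs(t_stat), df)
            half = stats.t.ppf(1 - alpha / 2, df) * se
        rows.append({
            "group1": g1, "group2": g2, "n1": len(a), "n2": len(b),
            "mean_diff": diff, "t": t_stat, "df": df, "p": p,
            "ci_low": diff - half, "ci_high": diff + half,
        })
    return pd.DataFrame(rows)


def partial_spearman(x, y, covariates=None,
                     method: str = "rank_then_residualize",
                     ) -> tuple[float, float, int]:
    """Partial Spearman correlation of x and y given covariates.

    Default pipeline: rank-transform x and y (average ranks for ties),
    OLS-residualize both rank vectors on [1, covariates], and correlate the
    residuals; p comes from ``t = rho * sqrt((n - 2 - p) / (1 - rho^2))``.
    ``method="residualize_then_rank"`` ranks the residuals of the raw
    values instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    keep = np.isfinite(x) & np.isfinite(y)
    if cov is not None:
        keep &= np.isfinite(cov).all(axis=1)
    x, y = x[keep], y[keep]
    cov = None if cov is None else cov[keep]
    n = x.size
    n_cov = 0 if cov is None else cov.shape[1]
    if n <= n_cov + 2:
        raise InsufficientDataError(
            f"partial Spearman needs n > p + 2; n={n}, p={n_cov}"
        )

    def _residualize(v: np.ndarray) -> np.ndarray:
        if cov is None:
            return v - v.mean()
        X = np.column_stack([np.ones(n), cov])
        beta = np.linalg.lstsq(X, v, rcond=None)[0]
        return v - X @ beta

    if method == "rank_then_residualize":
        rx = _residualize(stats.rankdata(x))
        ry = _residualize(stats.rankdata(y))
    elif method == "residualize_then_rank":
        rx = stats.rankdata(_residualize(x))
        ry = stats.rankdata(_residualize(y))
        rx, ry = rx - rx.mean(), ry - ry.mean()
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise UndefinedCorrelationError("constant input after ranking")
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - n_cov
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t_stat = rho_c * np.sqrt(df / (1 - rho_c ** 2))
    p = float(2 * stats.t.sf(abs(t_stat), df))
    return rho, p, n
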