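"""Subject-level models linking LC-related tau to cognition and amyloid.

Contains the five-test cognitive composite, Huber robust regression,
Johnson-Neyman moderation regions, percentile-bootstrap mediation and the
two-component Gaussian-mixture amyloid-positivity cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .exceptions import (
    DegenerateReferenceError,
    InsufficientDataError,
    UnimodalWarning,
)

__all__ = [
    "PACC5_COMPONENTS",
    "compose_pacc5",
    "robust_fit",
    "JNResult",
    "johnson_neyman",
    "MediationResult",
    "mediate",
    "gmm_abeta_threshold",
]

# MMSE, Logical Memory Delayed Recall, Digit Symbol, FCSRT free+total,
# Category Fluency
PACC5_COMPONENTS = (
    "mmse",
    "logical_memory_delayed",
    "digit_symbol",
    "fcsrt_free_total",
    "category_fluency",
)


def compose_pacc5(raw_scores: pd.DataFrame,
                  reference_stats: pd.DataFrame | None = None,
                  components: tuple[str, ...] = PACC5_COMPONENTS,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Five-test composite: mean of per-test z-scores.

    ``reference_stats`` must have a row per component with ``mean``/``sd``
    columns; if omitted, the stats are computed from ``raw_scores`` itself
    (the baseline-cohort convention). A subject missing any component gets
    a missing composite. Returns (scores, reference_stats_used).
    """
    missing_cols = [c for c in components if c not in raw_scores.columns]
    if missing_cols:
        raise KeyError(f"missing component columns: {missing_cols}")
    if reference_stats is None:
        reference_stats = pd.DataFrame({
            "mean": raw_scores[list(components)].mean(),
            "sd": raw_scores[list(components)].std(ddof=1),
        })
    zero_sd = reference_stats["sd"][reference_stats["sd"] == 0]
    if len(zero_sd):
        raise DegenerateReferenceError(
            f"zero reference sd for: {list(zero_sd.index)}"
        )
    out = pd.DataFrame(index=raw_scores.index)
    for comp in components:
        mu = reference_stats.loc[comp, "mean"]
        sd = reference_stats.loc[comp, "sd"]
        out[f"{comp}_z"] = (raw_scores[comp] - mu) / sd
    zcols = [f"{c}_z" for c in components]
    out["pacc5_z"] = out[zcols].mean(axis=1, skipna=False)
    return out, reference_stats


def _design(x_cols: list[np.ndarray]) -> np.ndarray:
    return np.column_stack([np.ones(len(x_cols[0]))] + x_cols)


def robust_fit(y, X, covariates=None, max_iter: int = 200,
               tol: float = 1e-8):
    """Huber M-estimation (tuning constant 1.345) via IRLS.

    ``X`` may be a vector (single predictor) or matrix. Returns the fitted
    statsmodels results object; ``params``/``bse`` follow the column order
    [const, predictors..., covariates...].
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cols = [X]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    full = np.column_stack(cols)
    keep = np.isfinite(y) & np.isfinite(full).all(axis=1)
    design = sm.add_constant(full[keep])
    model = sm.RLM(y[keep], design, M=sm.robust.norms.HuberT(t=1.345))
    return model.fit(maxiter=max_iter, tol=tol, conv="coefs")


@dataclass
class JNResult:
    """Johnson-Neyman region of significance for a moderated slope."""

    b1: float
    b3: float
    var_b1: float
    var_b3: float
    cov_b1_b3: float
    t_crit: float
    df: int
    boundaries: tuple[float, ...]
    region_type: str  # above | below | inside | outside | everywhere | nowhere

    def simple_slope(self, m: float) -> tuple[float, float]:
        """(slope, se) of the focal predictor at moderator value m."""
        slope = self.b1 + self.b3 * m
        var = self.var_b1 + m * m * self.var_b3 + 2 * m * self.cov_b1_b3
        return slope, float(np.sqrt(max(var, 0.0)))

    def significant_at(self, m: float) -> bool:
        slope, se = self.simple_slope(m)
        return bool(abs(slope) > self.t_crit * se)


def johnson_neyman(y, x, m, covariates=None,
                   alpha: float = 0.05) -> JNResult:
    """Moderator values at which the simple slope of x is significant.

    Fits ``y ~ x + m + x*m + covariates`` by OLS on the raw moderator scale
    and solves the quadratic boundary equation
    ``(b1 + b3 M)^2 = t_crit^2 Var(b1 + b3 M)`` for M.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    cols = [x, m, x * m]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    full = np.column_stack(cols)
    keep = np.isfinite(y) & np.isfinite(full).all(axis=1)
    X = _design([full[keep][:, i] for i in range(full.shape[1])])
    yy = y[keep]
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError(f"n={n} too small for {p} parameters")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ yy
    resid = yy - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    V = sigma2 * XtX_inv
    b1, b3 = float(beta[1]), float(beta[3])
    v1, v3, c13 = float(V[1, 1]), float(V[3, 3]), float(V[1, 3])
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))

    # (b1 + b3 M)^2 - t^2 (v1 + M^2 v3 + 2 M c13) = 0
    A = b3 * b3 - t_crit * t_crit * v3
    B = 2 * (b1 * b3 - t_crit * t_crit * c13)
    C = b1 * b1 - t_crit * t_crit * v1
    boundaries: tuple[float, ...]
    if abs(A) < 1e-300:
        boundaries = () if B == 0 else (-C / B,)
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            boundaries = ()
        else:
            r = np.sqrt(disc)
            boundaries = tuple(sorted(((-B - r) / (2 * A),
                                       (-B + r) / (2 * A))))

    result = JNResult(b1=b1, b3=b3, var_b1=v1, var_b3=v3, cov_b1_b3=c13,
                      t_crit=t_crit, df=df, boundaries=boundaries,
                      region_type="")
    result.region_type = _classify_region(result, m[keep])
    return result


def _classify_region(res: JNResult, m_obs: np.ndarray) -> str:
    """Region type over the observed moderator range.

    Boundaries outside [min(m), max(m)] do not change significance anywhere
    the moderator was actually observed, so they are ignored for
    classification (they remain reported in ``boundaries``).
    """
    if m_obs.size == 0:
        m_lo, m_hi = -np.inf, np.inf
    else:
        m_lo, m_hi = float(m_obs.min()), float(m_obs.max())
    inside = [b for b in res.boundaries if m_lo <= b <= m_hi]
    if len(inside) == 0:
        probe = float(np.median(m_obs)) if m_obs.size else 0.0
        return "everywhere" if res.significant_at(probe) else "nowhere"
    if len(inside) == 1:
        b = inside[0]
        above_probe = b + (m_hi - b) / 2.0 if np.isfinite(m_hi) else b + 1.0
        return "above" if res.significant_at(above_probe) else "below"
    lo, hi = inside[0], inside[-1]
    mid_sig = res.significant_at((lo + hi) / 2.0)
    return "inside" if mid_sig else "outside"


@dataclass
class MediationResult:
    a: float
    b: float
    c_prime: float
    total: float
    indirect: float
    prop_mediated: float
    ci: dict = field(default_factory=dict)       # name -> (low, high)
    boot_p: dict = field(default_factory=dict)   # name -> two-tailed p
    n_boot: int = 0
    n_used: int = 0
    seed: int | None = None
    prop_mediated_unstable: bool = False
    draws: dict | None = None


def _ols_beta_batch(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Batched OLS coefficients; X (b, n, p), y (b, n) -> (b, p)."""
    XtX = np.einsum("bni,bnj->bij", X, X)
    Xty = np.einsum("bni,bn->bi", X, y)
    return np.linalg.solve(XtX, Xty[..., None])[..., 0]


def mediate(x, mediator, y, covariates=None, n_boot: int = 5000,
            seed: int | np.random.Generator = 0,
            alpha: float = 0.05) -> MediationResult:
    """Percentile-bootstrap mediation with identical covariates in all paths.

    Paths: ``a`` from ``mediator ~ x + cov``; ``b`` and ``c'`` from
    ``y ~ x + mediator + cov``; ``total`` from ``y ~ x + cov``. With the
    same covariate set everywhere the OLS identity
    ``total = c' + a*b`` holds exactly on every bootstrap draw. Two-tailed
    bootstrap p-values are ``2 * min(P(draw < 0), P(draw > 0))``.
    """
    x = np.asarray(x, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    cov, _ = (None, []) if covariates is None else (np.asarray(
        covariates, dtype=float), [])
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    keep = np.isfinite(x) & np.isfinite(mediator) & np.isfinite(y)
    if cov is not None:
        keep &= np.isfinite(cov).all(axis=1)
    x, mediator, y = x[keep], mediator[keep], y[keep]
    cov = None if cov is None else cov[keep]
    n = x.size
    if n < 10:
        raise InsufficientDataError(f"mediation needs n >= 10, got {n}")

    def _paths(xs, ms, ys, cs):
        one = np.ones_like(xs)
        base = [one, xs] if cs is None else [one, xs, *cs.T]
        Xa = np.column_stack(base)
        a = np.linalg.lstsq(Xa, ms, rcond=None)[0][1]
        Xb = np.column_stack(base[:2] + [ms] + base[2:])
        bcoef = np.linalg.lstsq(Xb, ys, rcond=None)[0]
        b, c_prime = bcoef[2], bcoef[1]
        total = np.linalg.lstsq(Xa, ys, rcond=None)[0][1]
        return float(a), float(b), float(c_prime), float(total)

    a, b, c_prime, total = _paths(x, mediator, y, cov)
    indirect = a * b
    prop = indirect / total if total != 0 else np.nan

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.integers(0, n, size=(n_boot, n))
    one = np.ones((n_boot, n))
    xs, ms, ys = x[idx], mediator[idx], y[idx]
    if cov is None:
        Xa = np.stack([one, xs], axis=2)
        Xb = np.stack([one, xs, ms], axis=2)
    else:
        cvs = cov[idx]  # (n_boot, n, k)
        Xa = np.concatenate([one[..., None], xs[..., None], cvs], axis=2)
        Xb = np.concatenate(
            [one[..., None], xs[..., None], ms[..., None], cvs], axis=2)
    a_d = _ols_beta_batch(Xa, ms)[:, 1]
    bcoef = _ols_beta_batch(Xb, ys)
    b_d = bcoef[:, 2]
    cp_d = bcoef[:, 1]
    tot_d = _ols_beta_batch(Xa, ys)[:, 1]
    ind_d = a_d * b_d
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = np.where(tot_d != 0, ind_d / tot_d, np.nan)

    def _ci(draws):
        lo, hi = np.nanpercentile(draws,
                                  [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)

    def _p(draws):
        draws = draws[np.isfinite(draws)]
        if draws.size == 0:
            return np.nan
        return float(min(1.0, 2 * min(np.mean(draws < 0),
                                      np.mean(draws > 0))))

    named = {"a": a_d, "b": b_d, "c_prime": cp_d, "total": tot_d,
             "indirect": ind_d, "prop_mediated": prop_d}
    result = MediationResult(
        a=a, b=b, c_prime=c_prime, total=total, indirect=indirect,
        prop_mediated=float(prop),
        ci={k: _ci(v) for k, v in named.items()},
        boot_p={k: _p(v) for k, v in named.items()},
        n_boot=n_boot, n_used=n,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        prop_mediated_unstable=bool(
            abs(total) < 1e-8 or np.abs(tot_d).min() < 1e-8),
        draws=named,
    )
    return result


def gmm_abeta_threshold(values, n_init: int = 100,
                        random_state: int = 0,
                        merge_tol: float = 0.1) -> float:
    """Amyloid-positivity cutoff from a two-component 1-D Gaussian mixture.

    Fits by EM with k-means initialization and ``n_init`` restarts; the
    cutoff is the point between the component means where the posterior
    responsibility equals 0.5. If the components merge
    (|mu1 - mu2| < merge_tol * pooled sd) a :class:`UnimodalWarning` is
    issued and NaN returned.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise InsufficientDataError("need >= 4 values for the mixture fit")
    gm = GaussianMixture(n_components=2, n_init=n_init,
                         init_params="kmeans", random_state=random_state)
    gm.fit(values[:, None])
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    pooled = np.sqrt(np.mean(sd ** 2))
    if abs(mu[1] - mu[0]) < merge_tol * pooled:
        warnings.warn("mixture components merged; cutoff undefined",
                      UnimodalWarning)
        return float("nan")
    # a genuine two-population fit has a density dip between the means;
    # EM happily splits unimodal data into two overlapping components, so
    # require the fitted mixture itself to be bimodal
    grid = np.linspace(mu[0], mu[1], 512)
    dens = (w[0] * stats.norm.pdf(grid, mu[0], sd[0])
            + w[1] * stats.norm.pdf(grid, mu[1], sd[1]))
    if dens.min() >= min(dens[0], dens[-1]) * (1 - 1e-9):
        warnings.warn("fitted mixture is unimodal; cutoff undefined",
                      UnimodalWarning)
        return float("nan")

    def post_diff(v: float) -> float:
        # responsibility of the upper component minus 0.5
        log_p = (np.log(w) + stats.norm.logpdf(v, mu, sd))
        gap = np.clip(log_p[0] - log_p[1], -700, 700)
        p1 = 1.0 / (1.0 + np.exp(gap))
        return p1 - 0.5

    lo, hi = float(mu[0]), float(mu[1])
    f_lo, f_hi = post_diff(lo), post_diff(hi)
    if f_lo * f_hi > 0:  # equal-responsibility point outside (mu0, mu1)
        warnings.warn("no posterior-0.5 crossing between component means",
                      UnimodalWarning)
        return float("nan")
    return float(optimize.brentq(post_diff, lo, hi, xtol=1e-10))
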