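"""Association of network measures with clinical severity.

Patients' severity scores (YGTSS, 0-100) are related to a per-subject
network measure — typically the non-normalised global efficiency of the
unthresholded right-hemisphere network — by Pearson and Spearman
correlations, with and without age as a covariate (partial correlation by
residualising both variables on age), and by comparing a straight line
with a two-parameter exponential curve ``y = a * exp(b * x)`` through
small-sample-corrected AIC (AICc).  The relative likelihood of the better
model is ``exp((AICc_worse - AICc_better) / 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AssociationResult",
    "ModelFit",
    "ModelComparison",
    "correlate_with_score",
    "fit_and_compare",
    "relative_likelihood_from_aicc",
    "aicc",
]


@dataclass(frozen=True)
class AssociationResult:
    r: float
    p: float
    r_partial: float
    p_partial: float
    r_rank: float
    p_rank: float
    r_rank_partial: float
    p_rank_partial: float
    n: int


@dataclass(frozen=True)
class ModelFit:
    name: str
    params: tuple[float, ...]
    rss: float
    rmse: float
    r2_adj: float
    f_vs_constant: float
    f_p: float
    aicc: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.name == "linear":
            a, b = self.params
            return a + b * x
        a, b = self.params
        return a * np.exp(b * x)


@dataclass(frozen=True)
class ModelComparison:
    linear: ModelFit
    exponential: ModelFit
    preferred: str
    relative_likelihood: float


def _pearson_with_p(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df))


def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(covariate), covariate])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def correlate_with_score(
    measure: np.ndarray, score: np.ndarray, age: np.ndarray | None = None
) -> AssociationResult:
    """Pearson, Spearman and (optionally) age-partial correlations.

    Pairs with a missing value in either variable are dropped.  Partial
    correlations residualise both variables on age and correlate the
    residuals (p from a t distribution with n-3 degrees of freedom);
    rank-based analogues apply the same machinery to rank-transformed
    data.  Requires at least four complete pairs.
    """
    x = np.asarray(measure, dtype=float)
    y = np.asarray(score, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if age is not None:
        age = np.asarray(age, dtype=float)
        keep &= np.isfinite(age)
        age = None if age is None else age
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need at least four complete observation pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector")

    r, p = _pearson_with_p(x, y, n - 2)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    r_rank, p_rank = _pearson_with_p(rx, ry, n - 2)

    if age is None:
        r_part = p_part = r_rank_part = p_rank_part = np.nan
    else:
        a = np.asarray(age, dtype=float)[keep]
        r_part, p_part = _pearson_with_p(
            _residualize(x, a), _residualize(y, a), n - 3
        )
        ra = stats.rankdata(a)
        r_rank_part, p_rank_part = _pearson_with_p(
            _residualize(rx, ra), _residualize(ry, ra), n - 3
        )
    return AssociationResult(
        r=r, p=p, r_partial=r_part, p_partial=p_part,
        r_rank=r_rank, p_rank=p_rank,
        r_rank_partial=r_rank_part, p_rank_partial=p_rank_part, n=n,
    )


def aicc(rss: float, n: int, n_coef: int) -> float:
    """Small-sample-corrected AIC from a least-squares fit.

    ``k = n_coef + 1`` counts the residual variance as a parameter:
    ``AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)``.  Only differences in
    AICc between models on the same data are meaningful.
    """
    k = n_coef + 1
    if n - k - 1 <= 0:
        raise ValueError("too few points for the AICc correction")
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def relative_likelihood_from_aicc(aicc_a: float, aicc_b: float) -> float:
    """exp(|AICc difference| / 2): evidence for the lower-AICc model."""
    return float(np.exp(abs(aicc_a - aicc_b) / 2))


def _fit_stats(name, params, x, y, yhat) -> ModelFit:
    n, p = len(y), len(params)
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - rss / tss
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - p)
    f = ((tss - rss) / (p - 1)) / (rss / (n - p))
    f_p = float(stats.f.sf(f, p - 1, n - p))
    return ModelFit(
        name=name, params=tuple(float(v) for v in params),
        rss=rss, rmse=float(np.sqrt(rss / (n - p))),
        r2_adj=float(r2_adj), f_vs_constant=float(f), f_p=f_p,
        aicc=aicc(rss, n, p),
    )


def fit_and_compare(x: np.ndarray, y: np.ndarray, seed: int | None = 0) -> ModelComparison:
    """Fit linear and two-parameter exponential models; compare by AICc.

    The exponential fit ``y = a exp(b x)`` is nonlinear least squares,
    initialised from a log-linear regression of ln(y) on x and refined
    from five seeded, jittered restarts (best residual sum of squares
    wins).  Requires at least five points and strictly positive y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError("need at least five points")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires positive scores")

    coef = np.polyfit(x, y, 1)
    lin = _fit_stats("linear", (coef[1], coef[0]), x, y, np.polyval(coef, x))

    log_coef = np.polyfit(x, np.log(y), 1)
    start = np.array([np.exp(log_coef[1]), log_coef[0]])
    rng = np.random.default_rng(seed)

    def resid(theta):
        return theta[0] * np.exp(np.clip(theta[1] * x, -700, 700)) - y

    best = None
    for trial in range(6):
        theta0 = start if trial == 0 else start * (1 + 0.2 * rng.standard_normal(2))
        try:
            sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=10_000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise RuntimeError("exponential fit failed to converge from all starts")
    a, b = best[0]
    exp_fit = _fit_stats("exponential", (a, b), x, y, a * np.exp(b * x))

    if exp_fit.aicc <= lin.aicc:
        preferred = "exponential"
    else:
        preferred = "linear"
    return ModelComparison(
        linear=lin, exponential=exp_fit, preferred=preferred,
        relative_likelihood=relative_likelihood_from_aicc(lin.aicc, exp_fit.aicc),
    )
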