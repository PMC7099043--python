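"""Causal-effect estimators for two-sample Mendelian randomization.

Given a harmonized instrument set with per-SNP exposure effects
(beta_zx, se_zx) and outcome effects (beta_zy, se_zy), the causal effect of
the exposure on the outcome is estimated per SNP as the Wald ratio

    beta_xy = beta_zy / beta_zx

and pooled across instruments by:

* **simple median** — the equal-weight interpolated median of the Wald
  ratios, robust to up to half the instruments being invalid; its SE comes
  from a seeded parametric bootstrap of the summary statistics;
* **IVW** — inverse-variance weighting, algebraically the zero-intercept
  regression of beta_zy on beta_zx with weights 1/se_zy²; fixed-effect or
  multiplicative random-effects SEs;
* **MR-Egger** — the same weighted regression with a free intercept; a
  nonzero intercept estimates average directional pleiotropy.

Cochran's Q tests heterogeneity of the per-SNP ratios around the IVW
estimate.

Per-ratio standard errors: the default ``se_mode="delta"`` uses the
first-order delta approximation se_zy/|beta_zx|, which ignores the (here
negligible) uncertainty in the exposure beta.  ``se_mode="paper_eq2"`` is the
ratio of raw SEs, se_zy/se_zx — a convention found in some applied reports;
it is dimensionally inconsistent for a ratio estimate and is provided for
fidelity audits only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import Z95, round_half_away_from_zero, two_sided_normal_p
from .errors import ConfigurationError, EstimationError
from .harmonization import HarmonizedInstrument, HarmonizedSet

__all__ = [
    "WaldRatio",
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratio",
    "wald_ratios",
    "interpolated_weighted_median",
    "simple_median",
    "ivw",
    "mr_egger",
    "cochran_q",
]


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal-effect estimate beta_zy/beta_zx with its SE."""

    snp_id: str
    estimate: float
    se: float
    se_mode: str
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class MREstimate:
    """A pooled causal estimate: point value, SE, 95% CI and p-value."""

    method: str
    n_snps: int
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    pvalue: float
    seed: int | None = None
    n_boot: int | None = None

    @property
    def rounded(self) -> float:
        """Point estimate at the three-decimal reporting granularity."""
        return round_half_away_from_zero(self.estimate, 3)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q statistic with its chi-square p-value."""

    q: float
    df: int
    pvalue: float


def wald_ratio(instrument: HarmonizedInstrument, se_mode: str = "delta") -> WaldRatio:
    """Causal-effect estimate from a single instrument.

    ``se_mode="delta"`` gives se = se_zy/|beta_zx|; ``se_mode="paper_eq2"``
    gives the literal SE ratio se_zy/se_zx (see module docstring).
    """
    if instrument.beta_zx == 0:
        raise EstimationError(
            f"{instrument.snp_id}: Wald ratio undefined (exposure beta is 0)"
        )
    estimate = instrument.beta_zy / instrument.beta_zx
    if se_mode == "delta":
        se = instrument.se_zy / abs(instrument.beta_zx)
    elif se_mode == "paper_eq2":
        se = instrument.se_zy / instrument.se_zx
    else:
        raise ConfigurationError(f"unknown se_mode {se_mode!r}")
    return WaldRatio(
        snp_id=instrument.snp_id,
        estimate=estimate,
        se=se,
        se_mode=se_mode,
        ci_lower=estimate - Z95 * se,
        ci_upper=estimate + Z95 * se,
    )


def wald_ratios(hset: HarmonizedSet, se_mode: str = "delta") -> list[WaldRatio]:
    """Wald ratio for every instrument, in set order."""
    return [wald_ratio(i, se_mode) for i in hset]


def interpolated_weighted_median(values, weights=None) -> float:
    """Weighted median with linear interpolation between order statistics.

    Values are sorted ascending carrying their weights; the standardized
    cumulative weight of the j-th sorted value is p_j = (S_j - w_j/2)/S_n
    with S_j the running weight sum.  The median is the value at cumulative
    probability 0.5, linearly interpolated between the bracketing p_j
    (clamped to the extreme values outside [p_1, p_n]).  Equal weights give
    the ordinary sample median.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EstimationError("median of empty sequence")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != values.shape:
        raise ConfigurationError("values and weights length mismatch")
    if np.any(weights <= 0):
        raise ConfigurationError("weights must be strictly positive")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    p = (cum - 0.5 * w) / cum[-1]
    return float(np.interp(0.5, p, v))


def _bootstrap_medians(
    hset: HarmonizedSet, n_boot: int, seed: int
) -> np.ndarray:
    """Simple-median replicates under the parametric resampling model.

    Each replicate redraws beta_zx* ~ N(beta_zx, se_zx²) and
    beta_zy* ~ N(beta_zy, se_zy²) independently per instrument and study,
    then recomputes the equal-weight median of the replicate Wald ratios.
    With equal weights the interpolated median is the middle order statistic
    (odd n) or the mean of the two middle ones (even n), which vectorizes.

    Draws are assigned to instruments in rsID order, so the replicate stream
    — and hence the bootstrap SE — is invariant to the set's row order.
    """
    bzx, sezx, bzy, sezy = hset.arrays()
    canon = np.argsort(np.array(hset.snp_ids))
    bzx, sezx, bzy, sezy = bzx[canon], sezx[canon], bzy[canon], sezy[canon]
    rng = np.random.default_rng(seed)
    n = len(hset)
    bzx_star = rng.normal(bzx, sezx, size=(n_boot, n))
    bzy_star = rng.normal(bzy, sezy, size=(n_boot, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = bzy_star / bzx_star
    ratios = np.sort(ratios, axis=1)
    if n % 2:
        return ratios[:, n // 2]
    return 0.5 * (ratios[:, n // 2 - 1] + ratios[:, n // 2])


def simple_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Pooled causal estimate as the equal-weight median of Wald ratios.

    The point estimate is deterministic (independent of ``seed``); the SE is
    the standard deviation of the median across ``n_boot`` parametric
    bootstrap replicates of the summary statistics, the CI the usual
    normal-theory interval, and the p-value a two-sided normal test of
    estimate/SE.
    """
    if len(hset) < 1:
        raise EstimationError("simple_median needs at least 1 instrument")
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    ratios = [r.estimate for r in wald_ratios(hset)]
    estimate = interpolated_weighted_median(ratios)
    medians = _bootstrap_medians(hset, n_boot, seed)
    se = float(np.std(medians, ddof=1))
    pvalue = two_sided_normal_p(estimate / se) if se > 0 else (
        1.0 if estimate == 0 else two_sided_normal_p(np.inf)
    )
    return MREstimate(
        method="simple_median",
        n_snps=len(hset),
        estimate=estimate,
        se=se,
        ci_lower=estimate - Z95 * se,
        ci_upper=estimate + Z95 * se,
        pvalue=pvalue,
        seed=seed,
        n_boot=n_boot,
    )


def ivw(hset: HarmonizedSet, effects: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    The point estimate is the zero-intercept weighted regression of beta_zy
    on beta_zx with weights 1/se_zy² — identical for both ``effects`` modes.
    ``fixed`` uses the analytic SE (Σ beta_zx²/se_zy²)^(-1/2);
    ``multiplicative_random`` (default) inflates it by the residual standard
    deviation when that exceeds 1, the usual guard against underdispersion
    masking overdispersion.
    """
    n = len(hset)
    if n < 1:
        raise EstimationError("ivw needs at least 1 instrument")
    if effects not in ("fixed", "multiplicative_random"):
        raise ConfigurationError(f"unknown effects mode {effects!r}")
    if effects == "multiplicative_random" and n < 2:
        raise EstimationError("multiplicative_random IVW needs >= 2 instruments")
    bzx, _, bzy, sezy = hset.arrays()
    if np.any(bzx == 0):
        bad = [i.snp_id for i in hset if i.beta_zx == 0]
        raise EstimationError(f"zero exposure beta for {bad}")
    w = 1.0 / sezy**2
    denom = float(np.sum(w * bzx**2))
    estimate = float(np.sum(w * bzx * bzy)) / denom
    se = denom**-0.5
    if effects == "multiplicative_random":
        resid = bzy - estimate * bzx
        sigma2 = float(np.sum(w * resid**2)) / (n - 1)
        se *= max(1.0, sigma2) ** 0.5
    pvalue = two_sided_normal_p(estimate / se)
    return MREstimate(
        method="ivw_fe" if effects == "fixed" else "ivw_mre",
        n_snps=n,
        estimate=estimate,
        se=se,
        ci_lower=estimate - Z95 * se,
        ci_upper=estimate + Z95 * se,
        pvalue=pvalue,
    )


def mr_egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope, intercept) estimates.

    Fits beta_zy = θ0 + θ1·beta_zx by weighted least squares with weights
    1/se_zy².  The slope θ1 is the pleiotropy-adjusted causal effect; the
    intercept θ0 estimates the average directional pleiotropic effect —
    under valid instruments it should be indistinguishable from zero.
    SEs come from the weighted normal equations scaled by max(1, residual
    SD); p-values use the t distribution with n−2 degrees of freedom.

    The set should first pass through
    :func:`~mr2sample.harmonization.orient_exposure_positive` so the
    exposure axis has a consistent sign.
    """
    n = len(hset)
    if n < 3:
        raise EstimationError(f"mr_egger needs >= 3 instruments, got {n}")
    bzx, _, bzy, sezy = hset.arrays()
    if np.allclose(bzx, bzx[0]):
        raise EstimationError("mr_egger: degenerate design (all exposure betas equal)")
    w = 1.0 / sezy**2
    X = np.column_stack([np.ones(n), bzx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * bzy))
    resid = bzy - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov))
    df = n - 2

    def _estimate(method: str, est: float, se: float) -> MREstimate:
        p = float(2.0 * stats.t.sf(abs(est / se), df)) if se > 0 else 1.0
        return MREstimate(
            method=method,
            n_snps=n,
            estimate=est,
            se=se,
            ci_lower=est - Z95 * se,
            ci_upper=est + Z95 * se,
            pvalue=max(p, np.finfo(float).tiny),
        )

    slope = _estimate("egger_slope", float(coef[1]), float(ses[1]))
    intercept = _estimate("egger_intercept", float(coef[0]), float(ses[0]))
    return slope, intercept


def cochran_q(hset: HarmonizedSet, se_mode: str = "delta") -> HeterogeneityResult:
    """Cochran's Q heterogeneity test of the per-SNP Wald ratios.

    Q = Σ w_j (r_j − r_pooled)² with r_j the Wald ratios, w_j the inverse
    squared per-ratio SEs under ``se_mode``, and r_pooled the corresponding
    inverse-variance-weighted mean; the p-value is the upper chi-square tail
    on n−1 degrees of freedom.  With ``se_mode="delta"`` the weights are
    beta_zx²/se_zy² and r_pooled is the fixed-effect IVW estimate.
    """
    n = len(hset)
    if n < 2:
        raise EstimationError("cochran_q needs >= 2 instruments")
    ratios = wald_ratios(hset, se_mode=se_mode)
    r = np.array([x.estimate for x in ratios])
    w = np.array([1.0 / x.se**2 for x in ratios])
    pooled = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - pooled) ** 2))
    return HeterogeneityResult(
        q=q, df=n - 1, pvalue=float(stats.chi2.sf(q, n - 1))
    )
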