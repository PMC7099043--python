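"""Leave-one-out sensitivity analysis and the per-SNP forest table.

Leave-one-out re-estimates the pooled causal effect with each instrument
removed in turn; a large swing in the estimate flags an influential SNP.
The forest table lists every instrument's Wald ratio with its 95% CI plus a
pooled summary row — the data behind the conventional forest plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import stable_snp_seed
from .errors import ConfigurationError, EstimationError
from .estimators import MREstimate, ivw, simple_median, wald_ratios
from .harmonization import HarmonizedSet

__all__ = ["LooRow", "leave_one_out", "forest_table"]

_ESTIMATORS = {
    "simple_median": lambda hs, n_boot, seed: simple_median(hs, n_boot, seed),
    "ivw_fe": lambda hs, n_boot, seed: ivw(hs, "fixed"),
    "ivw_mre": lambda hs, n_boot, seed: ivw(hs, "multiplicative_random"),
}


@dataclass(frozen=True)
class LooRow:
    """Pooled estimate after removing one SNP, and its swing from the
    full-set estimate."""

    snp_removed: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    pvalue: float
    fluctuation: float


def _run(method: str, hset: HarmonizedSet, n_boot: int, seed) -> MREstimate:
    try:
        fn = _ESTIMATORS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown leave-one-out estimator {method!r}; "
            f"choose from {sorted(_ESTIMATORS)}"
        ) from None
    return fn(hset, n_boot, seed)


def leave_one_out(
    hset: HarmonizedSet,
    method: str = "simple_median",
    n_boot: int = 1000,
    seed: int = 0,
) -> list[LooRow]:
    """Re-run ``method`` on every (n−1)-instrument subset.

    Rows appear in instrument order.  Each row's bootstrap stream is derived
    from ``(seed, removed rsID)``, so results are independent of evaluation
    order; the fluctuation column is |estimate − full-set estimate| with the
    full set run on ``seed`` itself.
    """
    if len(hset) < 2:
        raise EstimationError("leave_one_out needs >= 2 instruments")
    full = _run(method, hset, n_boot, seed)
    rows = []
    for inst in hset:
        sub_seed = stable_snp_seed(seed, inst.snp_id)
        est = _run(method, hset.drop(inst.snp_id), n_boot, sub_seed)
        rows.append(
            LooRow(
                snp_removed=inst.snp_id,
                estimate=est.estimate,
                se=est.se,
                ci_lower=est.ci_lower,
                ci_upper=est.ci_upper,
                pvalue=est.pvalue,
                fluctuation=abs(est.estimate - full.estimate),
            )
        )
    return rows


def loo_frame(rows: list[LooRow]) -> pd.DataFrame:
    """Leave-one-out rows as a DataFrame (TSV-ready)."""
    return pd.DataFrame([vars(r) for r in rows])


def forest_table(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-SNP Wald ratios with 95% CIs plus a pooled simple-median row.

    Columns: snp_id, estimate, se, ci_lower, ci_upper; the final row carries
    the pooled estimate under snp_id ``"simple_median (pooled)"``.
    """
    if len(hset) < 1:
        raise EstimationError("forest_table needs >= 1 instrument")
    rows = [
        {
            "snp_id": r.snp_id,
            "estimate": r.estimate,
            "se": r.se,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
        }
        for r in wald_ratios(hset, se_mode="delta")
    ]
    pooled = simple_median(hset, n_boot=n_boot, seed=seed)
    rows.append(
        {
            "snp_id": "simple_median (pooled)",
            "estimate": pooled.estimate,
            "se": pooled.se,
            "ci_lower": pooled.ci_lower,
            "ci_upper": pooled.ci_upper,
        }
    )
    return pd.DataFrame(rows)
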