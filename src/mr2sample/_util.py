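"""Small numeric helpers used across modules."""

from __future__ import annotations

import hashlib

import numpy as np

#: 97.5% standard-normal quantile used for every 95% confidence interval.
Z95 = 1.959964


def round_half_away_from_zero(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Matches conventional scientific reporting (0.0005 -> 0.001,
    -0.0005 -> -0.001), unlike Python's banker's rounding.
    """
    if not np.isfinite(x):
        return float(x)
    scale = 10.0**ndigits
    # the trailing +0.0 normalizes -0.0 to 0.0
    return float(np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale) + 0.0


def two_sided_normal_p(z: float) -> float:
    """Two-sided p-value for a standard-normal statistic, floored away from 0."""
    from scipy import stats

    p = 2.0 * stats.norm.sf(abs(z))
    return float(max(p, np.finfo(float).tiny))


def stable_snp_seed(seed: int, snp_id: str) -> np.random.SeedSequence:
    """Derive a per-SNP random stream from a base seed and an rsID.

    Uses a BLAKE2 digest of the rsID so the stream depends only on
    (seed, snp_id), never on evaluation order or platform hash salt.
    """
    digest = hashlib.blake2b(snp_id.encode("utf-8"), digest_size=4).digest()
    return np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
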