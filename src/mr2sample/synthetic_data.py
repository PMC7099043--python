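"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws per-SNP true exposure effects b_zx, builds true outcome
effects b_zy = θ·b_zx + α with α the per-SNP directional pleiotropy
(Normal(pleiotropy_mean, pleiotropy_sd²); zero for valid instruments), and
observes both through independent Gaussian sampling noise at the two
studies' SE scales.  Positions and a block-structured r² table accompany the
datasets so LD clumping is testable.  Everything is reproducible from one
seed via an explicit stream-splitting scheme.

Defaults mirror a small cytokine-on-disease instrument set: 8 SNPs with
exposure betas of 0.06–0.10 (SE 0.01) and outcome effects on the ~1e-4
linear-model scale of a rare binary trait in a large cohort (SE 6.1e-5),
common alleles (MAF 0.3–0.5), a weak negative causal slope, no pleiotropy.

Summary statistics are simulated directly — no individual-level genotypes —
because the pipeline consumes only summary data and direct simulation keeps
the truth record exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .iv_selection import LDReference
from .summary_io import SummaryDataset, VariantAssociation

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_two_sample", "make_null_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth and noise parameters for one simulated dataset pair.

    ``se_zx``/``se_zy`` set the per-study SE scales directly; alternatively
    ``n_exposure``/``n_outcome`` give nominal sample sizes from which each
    SNP's SE is computed as (2·n·maf·(1−maf))^(−1/2) — the standard-normal
    trait approximation.  Sample sizes take precedence when provided.
    """

    n_snps: int = 8
    causal_slope: float = -0.001
    exposure_beta_range: tuple[float, float] = (0.06, 0.10)
    se_zx: float = 0.01
    se_zy: float = 6.1e-5
    n_exposure: int | None = None
    n_outcome: int | None = None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_ld_blocks: int = 2
    within_block_r2: float = 0.8
    between_block_r2: float = 0.0005
    maf_range: tuple[float, float] = (0.3, 0.5)
    positive_exposure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.se_zx < 0 or self.se_zy < 0:
            raise ConfigurationError("SE scales must be >= 0")
        lo, hi = self.exposure_beta_range
        if not (0 < lo <= hi):
            raise ConfigurationError("exposure_beta_range must be 0 < lo <= hi")
        for name in ("within_block_r2", "between_block_r2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1]")
        mlo, mhi = self.maf_range
        if not (0.0 < mlo <= mhi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if self.n_ld_blocks < 1 or self.n_ld_blocks > self.n_snps:
            raise ConfigurationError("n_ld_blocks must be in [1, n_snps]")
        for name in ("n_exposure", "n_outcome"):
            n = getattr(self, name)
            if n is not None and n < 2:
                raise ConfigurationError(f"{name} must be >= 2 when given")


@dataclass(frozen=True)
class SimulationTruth:
    """True per-SNP effects and the causal slope behind a simulated pair."""

    causal_slope: float
    snp_ids: list[str]
    beta_zx_true: np.ndarray
    beta_zy_true: np.ndarray
    pleiotropy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "beta_zx_true": self.beta_zx_true,
                "beta_zy_true": self.beta_zy_true,
                "pleiotropy": self.pleiotropy,
                "causal_slope": self.causal_slope,
            }
        )


_ALLELES = ("A", "C", "G", "T")


def _pvalue(beta: float, se: float) -> float | None:
    if se == 0:
        return None
    # floor at the smallest positive float: extreme z-scores underflow
    return float(max(2.0 * stats.norm.sf(abs(beta / se)), np.finfo(float).tiny))


def simulate_two_sample(
    cfg: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, LDReference, SimulationTruth]:
    """Generate an (exposure, outcome, LD reference, truth) quadruple.

    The base seed is split into four independent child streams — truth
    draws, exposure noise, outcome noise, allele/MAF assignment — so e.g.
    regenerating the outcome study alone is possible by reusing the same
    config.  SNPs are laid out in ``n_ld_blocks`` contiguous blocks on one
    chromosome (10 kb spacing within a block, 1 Mb between block starts);
    every within-block pair gets ``within_block_r2``, every between-block
    pair ``between_block_r2``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_truth, rng_exp, rng_out, rng_misc = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n = cfg.n_snps
    snp_ids = [f"snp{i + 1:04d}" for i in range(n)]

    lo, hi = cfg.exposure_beta_range
    bzx_true = rng_truth.uniform(lo, hi, size=n)
    if not cfg.positive_exposure:
        bzx_true *= rng_truth.choice([-1.0, 1.0], size=n)
    alpha = (
        rng_truth.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n)
        if (cfg.pleiotropy_mean != 0 or cfg.pleiotropy_sd > 0)
        else np.zeros(n)
    )
    bzy_true = cfg.causal_slope * bzx_true + alpha

    maf = rng_misc.uniform(*cfg.maf_range, size=n)
    ea = rng_misc.choice(_ALLELES, size=n)
    # pick a non-palindromic other allele so harmonization is unambiguous
    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    oa = [
        rng_misc.choice([b for b in _ALLELES if b not in (a, complement[a])])
        for a in ea
    ]
    if cfg.n_exposure is not None:
        se_zx = (2.0 * cfg.n_exposure * maf * (1 - maf)) ** -0.5
    else:
        se_zx = np.full(n, float(cfg.se_zx))
    if cfg.n_outcome is not None:
        se_zy = (2.0 * cfg.n_outcome * maf * (1 - maf)) ** -0.5
    else:
        se_zy = np.full(n, float(cfg.se_zy))

    bzx_obs = bzx_true + (rng_exp.normal(0.0, se_zx) if se_zx.any() else 0.0)
    bzy_obs = bzy_true + (rng_out.normal(0.0, se_zy) if se_zy.any() else 0.0)

    # positions: contiguous blocks; block b starts at 1 + b*1e6, SNPs 10 kb apart
    block = (np.arange(n) * cfg.n_ld_blocks) // n
    within_index = np.arange(n) - np.searchsorted(block, block)
    positions = 1 + block * 1_000_000 + within_index * 10_000

    def _dataset(trait, betas, ses, with_p):
        assocs = []
        for j in range(n):
            se_j = float(ses[j]) if ses[j] > 0 else None
            assocs.append(
                VariantAssociation(
                    snp_id=snp_ids[j],
                    chromosome="1",
                    position=int(positions[j]),
                    effect_allele=str(ea[j]),
                    other_allele=str(oa[j]),
                    eaf=float(maf[j]),
                    beta=float(betas[j]),
                    se=float(ses[j]) if ses[j] > 0 else 1e-300,
                    pvalue=_pvalue(float(betas[j]), float(ses[j])) if with_p else None,
                )
            )
        return SummaryDataset(trait, assocs, provenance=f"simulated, seed={cfg.seed}")

    exposure = _dataset("sim_exposure", bzx_obs, se_zx, with_p=True)
    outcome = _dataset("sim_outcome", bzy_obs, se_zy, with_p=True)

    pos_map = {snp_ids[j]: ("1", int(positions[j])) for j in range(n)}
    pairs = {}
    for i in range(n):
        for j in range(i + 1, n):
            r2 = (
                cfg.within_block_r2 if block[i] == block[j] else cfg.between_block_r2
            )
            pairs[frozenset((snp_ids[i], snp_ids[j]))] = r2
    ld = LDReference(pos_map, pairs)

    truth = SimulationTruth(
        causal_slope=cfg.causal_slope,
        snp_ids=snp_ids,
        beta_zx_true=bzx_true,
        beta_zy_true=bzy_true,
        pleiotropy=alpha,
    )
    return exposure, outcome, ld, truth


def make_null_config(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with no causal effect and no pleiotropy, for
    type-I-error experiments; all other fields (seed included) unchanged."""
    return replace(cfg, causal_slope=0.0, pleiotropy_mean=0.0, pleiotropy_sd=0.0)


def write_simulation(
    out_prefix: str | Path,
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDReference,
    truth: SimulationTruth,
) -> dict[str, Path]:
    """Write exposure.tsv, outcome.tsv, ld.tsv, positions.tsv, truth.tsv."""
    from .summary_io import write_summary_stats

    prefix = Path(out_prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": prefix / "exposure.tsv",
        "outcome": prefix / "outcome.tsv",
        "ld": prefix / "ld.tsv",
        "positions": prefix / "positions.tsv",
        "truth": prefix / "truth.tsv",
    }
    write_summary_stats(exposure, paths["exposure"])
    write_summary_stats(outcome, paths["outcome"])
    ld.to_files(paths["ld"], paths["positions"])
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
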