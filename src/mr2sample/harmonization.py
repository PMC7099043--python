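"""Align exposure and outcome summary statistics to a common effect allele.

Two-sample MR needs, for every instrument, the exposure effect beta_zx and
the outcome effect beta_zy expressed for the *same* allele.  When the outcome
study reports the opposite allele, its beta changes sign.  Palindromic SNPs
(A/T or C/G) with allele frequency near 0.5 cannot be oriented from summary
data alone and are dropped under the strict policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, HarmonizationError
from .summary_io import SummaryDataset

__all__ = ["HarmonizedInstrument", "HarmonizedSet", "harmonize", "orient_exposure_positive"]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: EAF window in which a palindromic SNP's strand is ambiguous.
PALINDROME_EAF_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One instrument with exposure and outcome effects on a shared allele."""

    snp_id: str
    effect_allele: str
    beta_zx: float
    se_zx: float
    beta_zy: float
    se_zy: float
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_zx > 0 and self.se_zy > 0):
            raise DataError(f"{self.snp_id}: SEs must be > 0")


class HarmonizedSet:
    """Ordered instrument set Z feeding every estimator."""

    def __init__(
        self,
        instruments: Sequence[HarmonizedInstrument],
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> None:
        ids = [i.snp_id for i in instruments]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate snp_id in harmonized set")
        self.instruments = list(instruments)
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self) -> Iterator[HarmonizedInstrument]:
        return iter(self.instruments)

    def __getitem__(self, snp_id: str) -> HarmonizedInstrument:
        for inst in self.instruments:
            if inst.snp_id == snp_id:
                return inst
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_zx, se_zx, beta_zy, se_zy) as float arrays in set order."""
        return (
            np.array([i.beta_zx for i in self.instruments]),
            np.array([i.se_zx for i in self.instruments]),
            np.array([i.beta_zy for i in self.instruments]),
            np.array([i.se_zy for i in self.instruments]),
        )

    def drop(self, snp_id: str) -> "HarmonizedSet":
        if snp_id not in self.snp_ids:
            raise KeyError(snp_id)
        return HarmonizedSet(
            [i for i in self.instruments if i.snp_id != snp_id],
            self.exposure_name,
            self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snp_id": i.snp_id,
                    "effect_allele": i.effect_allele,
                    "beta_zx": i.beta_zx,
                    "se_zx": i.se_zx,
                    "beta_zy": i.beta_zy,
                    "se_zy": i.se_zy,
                    "flipped": i.flipped,
                }
                for i in self.instruments
            ]
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HarmonizedSet({self.exposure_name!r} -> {self.outcome_name!r}, "
            f"n={len(self)})"
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    policy: str = "strict",
) -> HarmonizedSet:
    """Build the harmonized instrument set from two summary datasets.

    For each SNP present in both datasets:

    * same effect allele in both studies — copied through unchanged;
    * outcome effect allele equal to the exposure's other allele — outcome
      beta negated and the instrument flagged ``flipped``;
    * irreconcilable alleles, or a palindromic pair with EAF inside
      ``PALINDROME_EAF_WINDOW`` under ``policy="strict"`` — dropped and
      logged (``policy="permissive"`` keeps palindromes unflipped).

    When neither dataset carries an other-allele column the pair is treated
    as pre-aligned and passed through (one warning) — the situation of the
    bundled fixture, whose source reports both studies on a single EA column.
    """
    if policy not in ("strict", "permissive"):
        raise HarmonizationError(f"unknown policy {policy!r}")
    shared = [s for s in exposure.snp_ids if s in outcome]
    if not shared:
        raise HarmonizationError(
            f"no shared SNPs between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    no_other = all(
        exposure[s].other_allele is None and outcome[s].other_allele is None
        for s in shared
    )
    if no_other:
        log.warning(
            "no other_allele in either dataset: treating all %d shared SNPs "
            "as pre-aligned on the reported effect allele",
            len(shared),
        )

    instruments = []
    for snp in shared:
        exp, out = exposure[snp], outcome[snp]
        ea_x = exp.effect_allele.upper()
        ea_y = out.effect_allele.upper()
        beta_zy, flipped = out.beta, False

        if not no_other:
            if _is_palindromic(ea_x, exp.other_allele or "") or _is_palindromic(
                ea_y, out.other_allele or ""
            ):
                eaf = exp.eaf if exp.eaf is not None else out.eaf
                lo, hi = PALINDROME_EAF_WINDOW
                ambiguous = eaf is None or lo <= eaf <= hi
                if policy == "strict" and ambiguous:
                    log.info("dropping palindromic ambiguous SNP %s (eaf=%s)", snp, eaf)
                    continue
            if ea_y == ea_x:
                pass
            elif exp.other_allele is not None and ea_y == exp.other_allele.upper():
                beta_zy, flipped = -out.beta, True
            else:
                log.info(
                    "dropping %s: outcome EA %s matches neither exposure allele (%s/%s)",
                    snp, ea_y, ea_x, exp.other_allele,
                )
                continue
        instruments.append(
            HarmonizedInstrument(
                snp_id=snp,
                effect_allele=ea_x,
                beta_zx=exp.beta,
                se_zx=exp.se,
                beta_zy=beta_zy,
                se_zy=out.se,
                flipped=flipped,
            )
        )
    return HarmonizedSet(instruments, exposure.trait_name, outcome.trait_name)


def orient_exposure_positive(hset: HarmonizedSet) -> HarmonizedSet:
    """Negate both betas of every instrument whose exposure beta is negative.

    The double negation leaves every Wald ratio unchanged while giving the
    regression-based estimators (MR-Egger in particular) a consistently
    signed exposure axis.  Idempotent.
    """
    oriented = [
        replace(i, beta_zx=-i.beta_zx, beta_zy=-i.beta_zy) if i.beta_zx < 0 else i
        for i in hset
    ]
    return HarmonizedSet(oriented, hset.exposure_name, hset.outcome_name)
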