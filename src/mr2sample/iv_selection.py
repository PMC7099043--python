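"""Instrumental-variable selection from GWAS summary statistics.

Three filters, applied in order, turn an exposure GWAS into an instrument
set: (1) keep genome-wide-significant exposure SNPs (p < 5e-8); (2) prune
correlated SNPs by greedy LD clumping against a reference (r² > 0.001 within
a 10,000 kb window); (3) drop SNPs nominally associated with the outcome
(p ≤ 0.05), so instruments plausibly act on the outcome only through the
exposure.

The clumping rule is the standard one: a SNP is removed only when it is on
the same chromosome as a better-ranked index SNP, within the window, AND
correlated above the r² threshold.  Cross-chromosome pairs are always
independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, SelectionError
from .summary_io import SummaryDataset, VariantAssociation

__all__ = [
    "LDReference",
    "SelectionConfig",
    "filter_exposure_significant",
    "exclude_outcome_associated",
    "ld_clump",
    "select_instruments",
]

log = logging.getLogger(__name__)


class LDReference:
    """Pairwise r² lookup with SNP positions.

    ``r2(a, b)`` returns 1 for identical SNPs, the stored value for listed
    pairs, 0.0 for unlisted pairs on different chromosomes, and ``None`` for
    unlisted same-chromosome pairs (the caller's unknown-LD policy decides
    how to treat those).
    """

    def __init__(
        self,
        positions: Mapping[str, tuple[str, int]],
        r2_pairs: Mapping[frozenset, float] | None = None,
    ) -> None:
        self.positions = dict(positions)
        self._r2: dict[frozenset, float] = {}
        for pair, value in (r2_pairs or {}).items():
            pair = frozenset(pair)
            if len(pair) != 2:
                raise DataError(f"r2 pair must have two distinct SNPs: {set(pair)}")
            if not (0.0 <= value <= 1.0):
                raise DataError(f"r2 outside [0,1] for {set(pair)}: {value}")
            self._r2[pair] = float(value)

    @classmethod
    def from_files(cls, ld_path: str | Path, positions_path: str | Path) -> "LDReference":
        """Load from TSVs: (snp_a, snp_b, r2) triples and (snp_id, chromosome,
        position) rows."""
        pos_frame = pd.read_csv(positions_path, sep="\t", dtype={"chromosome": str})
        positions = {
            str(r.snp_id): (str(r.chromosome), int(r.position))
            for r in pos_frame.itertuples(index=False)
        }
        ld_frame = pd.read_csv(ld_path, sep="\t")
        pairs = {
            frozenset((str(r.snp_a), str(r.snp_b))): float(r.r2)
            for r in ld_frame.itertuples(index=False)
        }
        return cls(positions, pairs)

    def to_files(self, ld_path: str | Path, positions_path: str | Path) -> None:
        pd.DataFrame(
            [
                {"snp_id": s, "chromosome": c, "position": p}
                for s, (c, p) in self.positions.items()
            ]
        ).to_csv(positions_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"snp_a": min(pair), "snp_b": max(pair), "r2": v}
                for pair, v in self._r2.items()
            ]
        ).to_csv(ld_path, sep="\t", index=False)

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        value = self._r2.get(frozenset((a, b)))
        if value is not None:
            return value
        pos_a, pos_b = self.positions.get(a), self.positions.get(b)
        if pos_a and pos_b and pos_a[0] != pos_b[0]:
            return 0.0
        return None


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the three selection stages.

    ``unknown_ld`` controls same-chromosome pairs missing from the reference:
    ``"conservative"`` treats them as correlated (removed when in-window),
    ``"permissive"`` as independent.
    """

    exposure_p_max: float = 5e-8
    outcome_p_min: float = 0.05
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    unknown_ld: str = "conservative"

    def __post_init__(self) -> None:
        if not (0 < self.exposure_p_max):
            raise ConfigurationError("exposure_p_max must be > 0")
        if not (0 < self.outcome_p_min < 1):
            raise ConfigurationError("outcome_p_min must be in (0,1)")
        if not (0 < self.r2_max < 1):
            raise ConfigurationError("r2_max must be in (0,1)")
        if not (self.window_kb > 0):
            raise ConfigurationError("window_kb must be > 0")
        if self.unknown_ld not in ("conservative", "permissive"):
            raise ConfigurationError(f"unknown_ld policy {self.unknown_ld!r}")


def _pvalue(assoc: VariantAssociation) -> float:
    """Stated p-value, or the two-sided normal p derived from beta/se."""
    if assoc.pvalue is not None:
        return assoc.pvalue
    return float(2.0 * stats.norm.sf(abs(assoc.beta / assoc.se)))


def filter_exposure_significant(
    exposure: SummaryDataset, exposure_p_max: float = 5e-8
) -> SummaryDataset:
    """Keep SNPs with exposure p strictly below the genome-wide threshold."""
    keep = [a.snp_id for a in exposure if _pvalue(a) < exposure_p_max]
    if not keep:
        raise SelectionError(
            f"no SNP reaches exposure significance p < {exposure_p_max:g}; "
            "review the threshold or the exposure GWAS"
        )
    return exposure.subset(keep)


def exclude_outcome_associated(
    instruments: SummaryDataset,
    outcome: SummaryDataset,
    outcome_p_min: float = 0.05,
) -> SummaryDataset:
    """Drop instruments nominally associated with the outcome (p <= threshold).

    Instruments absent from the outcome dataset are dropped and logged —
    there is no proxy search.
    """
    keep = []
    for assoc in instruments:
        if assoc.snp_id not in outcome:
            log.info("dropping %s: absent from outcome dataset", assoc.snp_id)
            continue
        if _pvalue(outcome[assoc.snp_id]) > outcome_p_min:
            keep.append(assoc.snp_id)
        else:
            log.info(
                "dropping %s: outcome-associated (p <= %g)",
                assoc.snp_id, outcome_p_min,
            )
    return instruments.subset(keep)


def ld_clump(
    instruments: SummaryDataset,
    ld: LDReference,
    r2_max: float = 0.001,
    window_kb: float = 10_000.0,
    unknown_ld: str = "conservative",
) -> SummaryDataset:
    """Greedy LD clumping ranked by association p-value.

    SNPs are ranked ascending by p-value (ties broken by rsID); the
    best-ranked unremoved SNP becomes an index and every other unremoved SNP
    on its chromosome within ``window_kb`` with r² above ``r2_max`` is
    removed; this repeats until all SNPs are indices or removed.  The result
    depends only on the ranking, never on input row order, and is returned
    sorted by genomic position.
    """
    missing = [a.snp_id for a in instruments if a.snp_id not in ld.positions]
    if missing:
        raise SelectionError(f"SNP(s) absent from LD reference positions: {missing}")

    ranked = sorted(instruments, key=lambda a: (_pvalue(a), a.snp_id))
    removed: set[str] = set()
    indices: list[str] = []
    for snp in ranked:
        if snp.snp_id in removed:
            continue
        indices.append(snp.snp_id)
        chrom_i, pos_i = ld.positions[snp.snp_id]
        for other in ranked:
            if other.snp_id == snp.snp_id or other.snp_id in removed:
                continue
            chrom_o, pos_o = ld.positions[other.snp_id]
            if chrom_o != chrom_i:
                continue
            if abs(pos_o - pos_i) > window_kb * 1000:
                continue
            r2 = ld.r2(snp.snp_id, other.snp_id)
            correlated = (
                (unknown_ld == "conservative") if r2 is None else (r2 > r2_max)
            )
            if correlated:
                removed.add(other.snp_id)
    indices.sort(key=lambda s: ld.positions[s])
    by_id = {a.snp_id: a for a in instruments}
    return SummaryDataset(
        instruments.trait_name,
        [by_id[s] for s in indices],
        provenance=instruments.provenance,
    )


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDReference,
    cfg: SelectionConfig = SelectionConfig(),
) -> SummaryDataset:
    """Full selection pipeline: significance filter → LD clump → outcome
    exclusion.  Logs per-stage SNP counts; idempotent on its own output."""
    n0 = len(exposure)
    stage1 = filter_exposure_significant(exposure, cfg.exposure_p_max)
    stage2 = ld_clump(stage1, ld, cfg.r2_max, cfg.window_kb, cfg.unknown_ld)
    stage3 = exclude_outcome_associated(stage2, outcome, cfg.outcome_p_min)
    log.info(
        "instrument selection counts: input=%d significant=%d clumped=%d "
        "outcome_excluded=%d",
        n0, len(stage1), len(stage2), len(stage3),
    )
    return stage3
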