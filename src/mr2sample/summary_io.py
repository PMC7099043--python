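"""GWAS summary-statistics data model and tab-delimited I/O.

A GWAS summary file is tab-delimited with a header row, one row per SNP,
carrying at minimum an rsID, effect allele, beta and SE.  Column headers vary
between consortia, so :func:`read_summary_stats` accepts a mapping from the
package's standard field names to whatever the file calls them.

The bundled fixture is the 8-SNP instrument set relating circulating IL-18
(InCHIANTI/CHS GWAS) to osteoporosis case status (UK Biobank, self-reported),
shipped as a pre-aligned exposure/outcome TSV pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "VariantAssociation",
    "SummaryDataset",
    "read_summary_stats",
    "write_summary_stats",
    "load_fixture",
    "write_results",
    "STANDARD_FIELDS",
]

#: Standard field names; the first four are required on read.
STANDARD_FIELDS = (
    "snp_id",
    "effect_allele",
    "beta",
    "se",
    "chromosome",
    "position",
    "other_allele",
    "eaf",
    "pvalue",
)
_REQUIRED = ("snp_id", "effect_allele", "beta", "se")


@dataclass
class VariantAssociation:
    """One SNP's association statistics in a single GWAS.

    ``beta`` is the per-effect-allele effect on the trait in that study's
    units; ``se`` its standard error.  Optional fields are ``None`` when the
    source file does not provide them.
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    chromosome: str | None = None
    position: int | None = None
    other_allele: str | None = None
    eaf: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise DataError("snp_id must be non-empty")
        if not self.effect_allele:
            raise DataError(f"{self.snp_id}: effect_allele must be non-empty")
        if not math.isfinite(self.beta):
            raise DataError(f"{self.snp_id}: beta must be finite")
        if not (self.se > 0):
            raise DataError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise DataError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise DataError(f"{self.snp_id}: pvalue {self.pvalue} outside (0, 1]")


class SummaryDataset:
    """An ordered, rsID-keyed collection of :class:`VariantAssociation`."""

    def __init__(
        self,
        trait_name: str,
        associations: Iterable[VariantAssociation],
        provenance: str = "",
    ) -> None:
        self.trait_name = trait_name
        self.provenance = provenance
        self._by_id: dict[str, VariantAssociation] = {}
        for assoc in associations:
            if assoc.snp_id in self._by_id:
                raise DataError(
                    f"duplicate snp_id in {trait_name!r} dataset: {assoc.snp_id}"
                )
            self._by_id[assoc.snp_id] = assoc

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self._by_id.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._by_id

    def __getitem__(self, snp_id: str) -> VariantAssociation:
        return self._by_id[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return list(self._by_id)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        """New dataset restricted to ``snp_ids``, keeping this dataset's order."""
        keep = set(snp_ids)
        return SummaryDataset(
            self.trait_name,
            (a for a in self if a.snp_id in keep),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """All associations as a DataFrame in standard-field column order."""
        return pd.DataFrame(
            [{f: getattr(a, f) for f in STANDARD_FIELDS} for a in self]
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"SummaryDataset({self.trait_name!r}, n_snps={len(self)})"


def _coerce(row_num: int, snp: str, name: str, value, kind) -> object:
    if pd.isna(value):
        return None
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise DataError(
            f"row {row_num} ({snp}): cannot parse {name}={value!r}"
        ) from exc


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
) -> SummaryDataset:
    """Read a tab-delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Maps standard field names (:data:`STANDARD_FIELDS`) to the file's
        column headers.  Unmapped standard names default to themselves;
        optional fields whose columns are absent are simply left unset.
        Scientific notation is accepted in either ``6.15E-05`` or ``6.15e-5``
        spelling (both are plain floats).
    trait_name
        Defaults to the file's stem.

    Raises
    ------
    ConfigurationError
        A required column (snp_id, effect_allele, beta, se) is missing.
    DataError
        Duplicate rsIDs, non-positive SEs, or unparseable values; messages
        carry 1-based data row numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cmap = dict(column_map or {})
    resolved: dict[str, str] = {}
    for fname in STANDARD_FIELDS:
        header = cmap.get(fname, fname)
        if header in frame.columns:
            resolved[fname] = header
    missing = [f for f in _REQUIRED if f not in resolved]
    if missing:
        raise ConfigurationError(
            f"{path.name}: required column(s) not found: "
            + ", ".join(f"{f} (looked for {cmap.get(f, f)!r})" for f in missing)
        )

    dup = frame[resolved["snp_id"]][frame[resolved["snp_id"]].duplicated()]
    if not dup.empty:
        raise DataError(
            f"{path.name}: duplicate snp_id values: {sorted(set(dup))}"
        )

    associations = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        record = {f: row[h] for f, h in resolved.items()}
        snp = str(record["snp_id"])
        kwargs = {
            "snp_id": snp,
            "effect_allele": str(record["effect_allele"]),
            "beta": _coerce(i, snp, "beta", record["beta"], float),
            "se": _coerce(i, snp, "se", record["se"], float),
        }
        if kwargs["beta"] is None or kwargs["se"] is None:
            raise DataError(f"row {i} ({snp}): beta/se must be present")
        for fname, kind in (
            ("chromosome", str),
            ("position", lambda v: int(float(v))),
            ("other_allele", str),
            ("eaf", float),
            ("pvalue", float),
        ):
            if fname in record:
                kwargs[fname] = _coerce(i, snp, fname, record[fname], kind)
        associations.append(VariantAssociation(**kwargs))

    return SummaryDataset(
        trait_name or path.stem,
        associations,
        provenance=f"read from {path}",
    )


def write_summary_stats(dataset: SummaryDataset, path: str | Path) -> Path:
    """Write a dataset back to standard-column TSV (full float precision)."""
    path = Path(path)
    dataset.to_frame().to_csv(path, sep="\t", index=False)
    return path


def load_fixture() -> tuple[SummaryDataset, SummaryDataset]:
    """Load the bundled 8-SNP IL-18 / osteoporosis instrument set.

    Returns the exposure (IL-18, beta in log-concentration units per allele)
    and outcome (osteoporosis case status, linear-model beta per allele)
    datasets.  The two studies report effects on the same effect allele, so
    the pair is pre-aligned; no other-allele column is available.
    """
    data_dir = resources.files("mr2sample").joinpath("data")
    with resources.as_file(data_dir.joinpath("il18_exposure.tsv")) as p:
        exposure = read_summary_stats(p, trait_name="IL-18")
    with resources.as_file(data_dir.joinpath("osteoporosis_outcome.tsv")) as p:
        outcome = read_summary_stats(p, trait_name="Osteoporosis")
    exposure.provenance = "bundled fixture: IL-18 GWAS (InCHIANTI/CHS), 8 instruments"
    outcome.provenance = "bundled fixture: UK Biobank osteoporosis (self-reported)"
    return exposure, outcome


def write_results(estimates: Sequence, path: str | Path) -> Path:
    """Write pooled MR estimates as TSV.

    One row per :class:`~mr2sample.estimators.MREstimate` with columns
    method, n_snps, estimate, se, ci_lower, ci_upper, pvalue at full float
    precision, plus ``estimate_rounded`` at three decimals
    (half-away-from-zero) matching conventional reporting.
    """
    from ._util import round_half_away_from_zero

    if not estimates:
        raise ConfigurationError("write_results: empty estimate collection")
    path = Path(path)
    rows = []
    for est in estimates:
        rows.append(
            {
                "method": est.method,
                "n_snps": est.n_snps,
                "estimate": est.estimate,
                "se": est.se,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "pvalue": est.pvalue,
                "estimate_rounded": round_half_away_from_zero(est.estimate, 3),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
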