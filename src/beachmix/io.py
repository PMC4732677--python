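"""Isotope data model, delta-notation utilities and tidy CSV table I/O.

All isotope values are per-mil (‰) delta values: delta13C relative to Vienna
PeeDee Belemnite, delta15N relative to atmospheric N2,

    delta = (R_sample / R_standard - 1) * 1000,

where R is the heavy/light isotope ratio.

Tables use fixed one-row-per-observation schemas (RFC-4180 CSV, UTF-8,
'.' decimal, missing values as empty fields):

    sites.csv            site,width_m,slope_deg,grain_mm,wrack_g,burrow_density
    signatures.csv       site,taxon,replicate_id,d13C,d15N
    consumers.csv        site,crab_id,d13C,d15N
    wrack_components.csv site,component,dry_mass_prop,d13C,d15N

Lines starting with ``#`` are treated as comment headers on read and may be
written by the pipeline to record provenance (version, seed, config hash).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The three principal prey taxa, in canonical order (swash filter-feeder,
#: wrack-associated detritivore, swash suspension-feeder).
PREY_TAXA = ("mole_crab", "amphipod", "coquina")
CONSUMER_TAXON = "consumer"

#: Soft plausibility envelopes for marine/coastal tissue (‰). Values outside
#: trigger a warning, never a rejection — exotic substrates exist.
_D13C_PLAUSIBLE = (-60.0, 10.0)
_D15N_PLAUSIBLE = (-10.0, 30.0)

SITES_COLUMNS = ["site", "width_m", "slope_deg", "grain_mm", "wrack_g", "burrow_density"]
SIGNATURES_COLUMNS = ["site", "taxon", "replicate_id", "d13C", "d15N"]
CONSUMERS_COLUMNS = ["site", "crab_id", "d13C", "d15N"]
WRACK_COLUMNS = ["site", "component", "dry_mass_prop", "d13C", "d15N"]


class DataError(ValueError):
    """A table violates its schema or a value violates its domain."""


@dataclass(frozen=True)
class IsotopeSignature:
    """Paired carbon/nitrogen delta values (‰) for one specimen or material."""

    delta13C: float
    delta15N: float
    imputed: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta13C) and math.isfinite(self.delta15N)):
            raise DataError(
                f"non-finite isotope signature: d13C={self.delta13C}, d15N={self.delta15N}"
            )
        if not _D13C_PLAUSIBLE[0] <= self.delta13C <= _D13C_PLAUSIBLE[1]:
            warnings.warn(
                f"delta13C = {self.delta13C} ‰ outside plausible range {_D13C_PLAUSIBLE}",
                stacklevel=2,
            )
        if not _D15N_PLAUSIBLE[0] <= self.delta15N <= _D15N_PLAUSIBLE[1]:
            warnings.warn(
                f"delta15N = {self.delta15N} ‰ outside plausible range {_D15N_PLAUSIBLE}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SignatureSummary:
    """Per site x taxon isotope summary: mean, sample SD (n-1) and n.

    SDs are ``None`` when undefined (n < 2) or for imputed entries with no
    replicate structure of their own.
    """

    site: str
    taxon: str
    mean_d13C: float
    mean_d15N: float
    sd_d13C: float | None
    sd_d15N: float | None
    n: int
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.n < 0:
            raise DataError(f"negative replicate count n={self.n}")
        for sd in (self.sd_d13C, self.sd_d15N):
            if sd is not None and sd < 0:
                raise DataError(f"negative SD {sd}")


@dataclass(frozen=True)
class SiteRecord:
    """Physical description of one beach site."""

    site: str
    width_m: float
    slope_deg: float
    grain_mm: float
    wrack_g: float
    burrow_density: float | None = None

    def __post_init__(self) -> None:
        if self.width_m <= 0:
            raise DataError(f"site {self.site}: width must be positive, got {self.width_m}")
        if self.slope_deg < 0:
            raise DataError(f"site {self.site}: negative slope {self.slope_deg}")
        if self.grain_mm <= 0:
            raise DataError(f"site {self.site}: grain size must be positive, got {self.grain_mm}")
        if self.wrack_g < 0:
            raise DataError(f"site {self.site}: negative wrack biomass {self.wrack_g}")
        if self.burrow_density is not None and self.burrow_density < 0:
            raise DataError(f"site {self.site}: negative burrow density {self.burrow_density}")


def delta_value(r_sample: float, r_standard: float) -> float:
    """Convert an isotope ratio to delta notation (‰).

    Parameters
    ----------
    r_sample : heavy/light isotope ratio of the sample.
    r_standard : heavy/light ratio of the international standard (VPDB for
        carbon, air N2 for nitrogen). Must be positive.
    """
    if r_standard <= 0:
        raise DataError(f"standard ratio must be positive, got {r_standard}")
    return (r_sample / r_standard - 1.0) * 1000.0


def summarize_signatures(
    replicates: pd.DataFrame | Iterable[tuple[str, str, IsotopeSignature]],
) -> list[SignatureSummary]:
    """Aggregate replicate signatures into per site x taxon summaries.

    Accepts either a signatures-schema DataFrame (columns site, taxon, d13C,
    d15N) or an iterable of ``(site, taxon, IsotopeSignature)`` tuples.
    Means and sample SDs (n-1 denominator) are computed per isotope; the SD
    is recorded as missing when n = 1. Groups with no finite values are
    skipped with a warning.
    """
    if not isinstance(replicates, pd.DataFrame):
        rows = [
            {"site": s, "taxon": t, "d13C": sig.delta13C, "d15N": sig.delta15N}
            for s, t, sig in replicates
        ]
        replicates = pd.DataFrame(rows, columns=["site", "taxon", "d13C", "d15N"])

    out: list[SignatureSummary] = []
    for (site, taxon), grp in replicates.groupby(["site", "taxon"], sort=True):
        vals = grp[["d13C", "d15N"]].dropna()
        n = len(vals)
        if n == 0:
            logger.warning("empty signature group (%s, %s) skipped", site, taxon)
            continue
        sd_c = float(vals["d13C"].std(ddof=1)) if n >= 2 else None
        sd_n = float(vals["d15N"].std(ddof=1)) if n >= 2 else None
        out.append(
            SignatureSummary(
                site=str(site),
                taxon=str(taxon),
                mean_d13C=float(vals["d13C"].mean()),
                mean_d15N=float(vals["d15N"].mean()),
                sd_d13C=sd_c,
                sd_d15N=sd_n,
                n=n,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[SignatureSummary]) -> pd.DataFrame:
    """Tabulate SignatureSummary objects (one row per site x taxon)."""
    return pd.DataFrame(
        [
            {
                "site": s.site,
                "taxon": s.taxon,
                "mean_d13C": s.mean_d13C,
                "mean_d15N": s.mean_d15N,
                "sd_d13C": np.nan if s.sd_d13C is None else s.sd_d13C,
                "sd_d15N": np.nan if s.sd_d15N is None else s.sd_d15N,
                "n": s.n,
                "imputed": int(s.imputed),
            }
            for s in summaries
        ]
    )


def mix_wrack_signature(
    components: Sequence[tuple[IsotopeSignature, float]],
) -> IsotopeSignature:
    """Proportionally mix wrack-component signatures into one basal signature.

    Weights are dry-mass proportions; they are renormalized to sum to 1.
    The mixture is the weighted arithmetic mean per isotope.
    """
    if not components:
        raise DataError("cannot mix an empty component list")
    weights = np.array([w for _, w in components], dtype=float)
    if np.any(weights < 0):
        raise DataError("negative dry-mass proportion")
    total = weights.sum()
    if total <= 0:
        raise DataError("all-zero dry-mass proportions")
    weights /= total
    d13c = float(np.dot(weights, [sig.delta13C for sig, _ in components]))
    d15n = float(np.dot(weights, [sig.delta15N for sig, _ in components]))
    return IsotopeSignature(d13c, d15n)


# ---------------------------------------------------------------------------
# CSV readers / writers


def _read_table(path: str | Path, columns: list[str], required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    logger.info("read %d rows from %s", len(df), path)
    extra = [c for c in df.columns if c not in columns]
    return df[[c for c in columns if c in df.columns] + extra]


def _write_table(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    logger.info("wrote %d rows to %s", len(df), path)


def read_sites(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SITES_COLUMNS, SITES_COLUMNS[:5])


def write_sites(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    _write_table(df, path, header_lines)


def read_signatures(path: str | Path) -> pd.DataFrame:
    return _read_table(path, SIGNATURES_COLUMNS, SIGNATURES_COLUMNS)


def write_signatures(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    _write_table(df, path, header_lines)


def read_consumers(path: str | Path) -> pd.DataFrame:
    return _read_table(path, CONSUMERS_COLUMNS, CONSUMERS_COLUMNS)


def write_consumers(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    _write_table(df, path, header_lines)


def read_wrack_components(path: str | Path) -> pd.DataFrame:
    return _read_table(path, WRACK_COLUMNS, WRACK_COLUMNS)


def write_wrack_components(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    _write_table(df, path, header_lines)
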