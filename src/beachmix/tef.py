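"""Site-specific trophic enrichment factors and missing-source imputation.

The nitrogen trophic enrichment factor (TEF, also called the discrimination
factor) at a site is the average of the differences between the consumer's
mean delta15N and each of its three principal prey sources' mean delta15N;
its SD is the sample SD (n-1, n=3) of those three differences. No carbon
TEF is applied (carbon shows little to no trophic enrichment in these
systems), so the carbon entry is fixed at mean 0, SD 0.

Amphipod tissue can be unobtainable at sites with low or dry wrack. Missing
amphipod source signatures are imputed from the site's proportionally mixed
wrack signature: the carbon value passes through unchanged (no trophic
fractionation assumed) and the nitrogen value comes from a linear
calibration fitted between wrack and amphipod delta15N at sites where both
were measured.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import PREY_TAXA, DataError, IsotopeSignature, SignatureSummary

__all__ = [
    "TEFSpec",
    "NCalibration",
    "MissingSourceError",
    "estimate_tef",
    "fit_n_calibration",
    "impute_amphipod",
    "impute_missing_summaries",
]

#: Fallback SD (‰) assigned to an imputed source when no measured per-site
#: amphipod SDs exist anywhere in the dataset.
DEFAULT_IMPUTED_SD = 0.5


class MissingSourceError(DataError):
    """A required source signature is absent (imputation must run first)."""


@dataclass(frozen=True)
class TEFSpec:
    """Per-isotope trophic enrichment: nitrogen (mean, SD); carbon fixed (0, 0)."""

    nitrogen_mean: float
    nitrogen_sd: float
    carbon_mean: float = 0.0
    carbon_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.carbon_mean != 0.0 or self.carbon_sd != 0.0:
            raise DataError("carbon TEF is fixed at (0, 0)")
        if self.nitrogen_sd < 0:
            raise DataError("nitrogen TEF SD must be >= 0")


@dataclass(frozen=True)
class NCalibration:
    """Linear wrack -> amphipod delta15N calibration (OLS)."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise DataError("calibration requires at least 3 pairs")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise DataError(f"R^2 out of [0, 1]: {self.r_squared}")

    def predict(self, wrack_d15n: float) -> float:
        return self.slope * wrack_d15n + self.intercept


def estimate_tef(
    consumer_summary: SignatureSummary,
    source_summaries: Mapping[str, SignatureSummary],
) -> TEFSpec:
    """Estimate the site's nitrogen TEF from consumer and source means.

    Parameters
    ----------
    consumer_summary : site-level consumer (ghost crab) summary.
    source_summaries : mapping taxon -> summary; must contain all of
        ``mole_crab``, ``amphipod`` and ``coquina`` (imputed entries count).

    The estimate is translation-equivariant: shifting the consumer and all
    sources by a constant leaves the TEF unchanged.
    """
    for taxon in PREY_TAXA:
        if taxon not in source_summaries:
            raise MissingSourceError(
                f"site {consumer_summary.site}: missing source '{taxon}' — "
                "impute it before estimating the TEF"
            )
    diffs = [
        consumer_summary.mean_d15N - source_summaries[t].mean_d15N for t in PREY_TAXA
    ]
    return TEFSpec(
        nitrogen_mean=float(np.mean(diffs)),
        nitrogen_sd=float(statistics.stdev(diffs)),
    )


def fit_n_calibration(pairs: Sequence[tuple[float, float]]) -> NCalibration:
    """Fit the OLS line amphipod delta15N = slope * wrack delta15N + intercept.

    Requires at least 3 (wrack, amphipod) pairs and non-degenerate predictor
    variance. The p-value is the two-sided test of zero slope.
    """
    if len(pairs) < 3:
        raise DataError(f"need >= 3 calibration pairs, got {len(pairs)}")
    x = np.asarray([p[0] for p in pairs], float)
    y = np.asarray([p[1] for p in pairs], float)
    if np.ptp(x) == 0:
        raise DataError("zero variance in wrack delta15N: cannot calibrate")
    if np.ptp(y) == 0:
        # constant response: flat line fits perfectly but explains nothing
        return NCalibration(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                            n=len(pairs), p_value=1.0)
    res = stats.linregress(x, y)
    return NCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(1.0, float(res.rvalue**2)),
        n=len(pairs),
        p_value=float(res.pvalue),
    )


def impute_amphipod(
    wrack_signature: IsotopeSignature, calibration: NCalibration, site: str | None = None
) -> IsotopeSignature:
    """Impute a site's amphipod signature from its mixed wrack signature.

    Carbon passes through unchanged (no trophic fractionation); nitrogen is
    the calibration line evaluated at the wrack delta15N. The returned
    signature carries ``imputed=True``.
    """
    if wrack_signature is None:
        raise MissingSourceError(
            f"site {site or '<unknown>'}: no wrack signature available for imputation"
        )
    return IsotopeSignature(
        delta13C=wrack_signature.delta13C,
        delta15N=calibration.predict(wrack_signature.delta15N),
        imputed=True,
    )


def impute_missing_summaries(
    summaries: Sequence[SignatureSummary],
    wrack_by_site: Mapping[str, IsotopeSignature],
    calibration: NCalibration,
) -> list[SignatureSummary]:
    """Fill in amphipod summaries for sites that lack measured amphipod tissue.

    Imputed entries get the mean of the measured per-site amphipod SDs
    elsewhere in the dataset (fallback 0.5 ‰ when none exist), n = 0 and a
    persistent imputed flag. Sites without a wrack signature raise.
    """
    have_amph = {s.site for s in summaries if s.taxon == "amphipod"}
    all_sites = sorted({s.site for s in summaries})
    sd_c_pool = [
        s.sd_d13C for s in summaries if s.taxon == "amphipod" and s.sd_d13C is not None
    ]
    sd_n_pool = [
        s.sd_d15N for s in summaries if s.taxon == "amphipod" and s.sd_d15N is not None
    ]
    sd_c = float(np.mean(sd_c_pool)) if sd_c_pool else DEFAULT_IMPUTED_SD
    sd_n = float(np.mean(sd_n_pool)) if sd_n_pool else DEFAULT_IMPUTED_SD

    out = list(summaries)
    for site in all_sites:
        if site in have_amph:
            continue
        if site not in wrack_by_site:
            raise MissingSourceError(f"site {site}: no wrack signature to impute amphipod from")
        sig = impute_amphipod(wrack_by_site[site], calibration, site=site)
        out.append(
            SignatureSummary(
                site=site,
                taxon="amphipod",
                mean_d13C=sig.delta13C,
                mean_d15N=sig.delta15N,
                sd_d13C=sd_c,
                sd_d15N=sd_n,
                n=0,
                imputed=True,
            )
        )
    return out
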