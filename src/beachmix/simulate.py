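"""Forward simulation of a sandy-beach food-web scenario with known truth.

The generator emulates a gradient of beach morphology: a set of sites whose
width spans a configured range, with foreshore slope and median grain size
co-varying negatively with width (narrow beaches are steep and coarse,
wide beaches flat and fine). Three prey resources follow availability
curves over width — a mole-crab availability that declines linearly with
width, an amphipod availability that peaks (Gaussian) at intermediate
width where damp macrophyte wrack accumulates, and a coquina-clam
availability that rises linearly with width. Consumer (ghost crab) burrow
density follows its own Gaussian peak at intermediate width.

Per site, true diet proportions are the normalized availability scores.
Source replicate signatures are drawn around site-shifted taxon means, and
each consumer signature is drawn from the mixing model's forward
distribution

    delta_j ~ Normal( sum_k p_k (s_jk + c_jk),
                      sum_k p_k^2 (sigma_jk^2 + tau_jk^2) + sigma_res_j^2 )

so every downstream stage (TEF estimation, imputation, Bayesian mixing,
trophic position, gradient regressions) can be checked against known
ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as bio

__all__ = [
    "AvailabilityParams",
    "ScenarioConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "ConfigError",
    "simulate_sites",
    "simulate_truth",
    "simulate_isotopes",
    "simulate_scenario",
]


class ConfigError(ValueError):
    """Invalid scenario configuration."""


def _gauss(x: np.ndarray | float, center: float, spread: float, amplitude: float):
    return amplitude * np.exp(-0.5 * ((x - center) / spread) ** 2)


@dataclass(frozen=True)
class AvailabilityParams:
    """Resource-availability curves over beach width (arbitrary relative units).

    Mole crab: linear decline ``intercept + slope * width``; coquina: linear
    rise; amphipod and predator (burrow) density: Gaussian peaks at
    intermediate width. Negative curve values are clipped to zero when used.
    """

    mole_slope: float
    mole_intercept: float
    coq_slope: float
    coq_intercept: float
    amph_center: float = 40.0
    amph_spread: float = 12.0
    amph_amplitude: float = 1.0
    predator_center: float = 40.0
    predator_spread: float = 15.0
    predator_amplitude: float = 1.0

    @classmethod
    def for_width_range(cls, low: float, high: float) -> "AvailabilityParams":
        """Default curves: mole crab 1 -> 0 and coquina 0 -> 1 across the range."""
        span = high - low
        return cls(
            mole_slope=-1.0 / span,
            mole_intercept=high / span,
            coq_slope=1.0 / span,
            coq_intercept=-low / span,
        )

    def __post_init__(self) -> None:
        for name in ("amph_amplitude", "predator_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("amph_spread", "predator_spread"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def mole(self, width):
        return self.mole_intercept + self.mole_slope * np.asarray(width, float)

    def amph(self, width):
        return _gauss(np.asarray(width, float), self.amph_center, self.amph_spread, self.amph_amplitude)

    def coq(self, width):
        return self.coq_intercept + self.coq_slope * np.asarray(width, float)

    def predator(self, width):
        return _gauss(
            np.asarray(width, float),
            self.predator_center,
            self.predator_spread,
            self.predator_amplitude,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Defaults describe a 16-site gradient with widths spanning 15.7-106.6 m,
    source delta15N bases (5.3, 3.8, 5.9) ‰ for mole crab / amphipod /
    coquina, a true nitrogen trophic enrichment of 2.3 +/- 0.3 ‰ and no
    carbon enrichment, replicate SD 0.5 ‰, site-to-site source drift 0.5 ‰
    and residual consumer SD 0.3 ‰ per isotope.
    """

    n_sites: int = 16
    width_range: tuple[float, float] = (15.7, 106.6)
    width_jitter: float = 0.0
    availability: AvailabilityParams | None = None
    #: taxon -> (delta13C, delta15N) base means in ‰
    source_mean_bases: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "mole_crab": (-14.8, 5.3),
            "amphipod": (-17.9, 3.8),
            "coquina": (-21.5, 5.9),
        }
    )
    source_sd: float = 0.5
    site_shift_sd: float = 0.5
    tef_true: tuple[float, float] = (2.3, 0.3)  # delta15N (mean, SD) ‰
    residual_sd: tuple[float, float] = (0.3, 0.3)  # per isotope (C, N) ‰
    n_source_reps: tuple[int, int] = (2, 9)
    n_consumers: tuple[int, int] = (3, 7)
    #: sites (count, taken from the start of the site list) whose amphipod
    #: tissue is withheld from the signature table, to exercise imputation
    n_missing_amphipod_sites: int = 0
    #: true wrack -> amphipod delta15N calibration used to generate wrack
    wrack_calibration: tuple[float, float] = (1.433, 2.242)
    wrack_scale_g: float = 400.0
    wrack_noise_g: float = 30.0
    slope_range_deg: tuple[float, float] = (2.4, 17.2)
    grain_range_mm: tuple[float, float] = (0.1875, 1.5)
    burrow_scale: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ConfigError("n_sites must be >= 2")
        low, high = self.width_range
        if not low < high:
            raise ConfigError(f"width_range low must be < high, got {self.width_range}")
        if low <= 0:
            raise ConfigError("widths must be positive")
        for name in ("source_sd", "site_shift_sd", "width_jitter", "wrack_noise_g"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.tef_true[1] < 0 or any(s < 0 for s in self.residual_sd):
            raise ConfigError("SDs must be >= 0")
        for rng_ in (self.n_source_reps, self.n_consumers):
            if rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ConfigError(f"invalid count range {rng_}")
        if set(self.source_mean_bases) != set(bio.PREY_TAXA):
            raise ConfigError(f"source_mean_bases must have keys {bio.PREY_TAXA}")
        if self.availability is None:
            object.__setattr__(
                self, "availability", AvailabilityParams.for_width_range(low, high)
            )

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible RNG substream for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for one simulated scenario.

    ``diet`` has one row per site with columns p_mole_crab, p_amphipod,
    p_coquina (each row on the simplex); ``source_means`` holds the
    site-shifted true source means per isotope.
    """

    diet: pd.DataFrame  # site, p_<taxon>
    source_means: pd.DataFrame  # site, taxon, d13C, d15N
    source_sd: float
    tef: tuple[float, float]
    residual_sd: tuple[float, float]

    def diet_vector(self, site: str) -> np.ndarray:
        row = self.diet.loc[self.diet["site"] == site].iloc[0]
        return np.array([row[f"p_{t}"] for t in bio.PREY_TAXA])


@dataclass
class SyntheticDataset:
    """Simulated tables in the standard tidy schemas, plus the truth ledger."""

    sites: pd.DataFrame
    signatures: pd.DataFrame
    consumers: pd.DataFrame
    wrack_components: pd.DataFrame
    truth: SyntheticTruth

    def write(self, out_dir: str | Path, header_lines: Sequence[str] = ()) -> dict[str, Path]:
        out_dir = Path(out_dir)
        paths = {
            "sites": out_dir / "sites.csv",
            "signatures": out_dir / "signatures.csv",
            "consumers": out_dir / "consumers.csv",
            "wrack_components": out_dir / "wrack_components.csv",
        }
        bio.write_sites(self.sites, paths["sites"], header_lines)
        bio.write_signatures(self.signatures, paths["signatures"], header_lines)
        bio.write_consumers(self.consumers, paths["consumers"], header_lines)
        bio.write_wrack_components(self.wrack_components, paths["wrack_components"], header_lines)
        truth_path = out_dir / "truth_diet.csv"
        bio._write_table(self.truth.diet, truth_path, header_lines)
        paths["truth_diet"] = truth_path
        return paths


def simulate_sites(config: ScenarioConfig) -> pd.DataFrame:
    """Generate per-site physical records along the width gradient.

    Widths are evenly spaced over ``width_range`` then jittered by
    ``width_jitter`` (clipped back into range). Slope and grain size decline
    with width; wrack biomass follows the amphipod availability curve and
    burrow density the predator curve, both with noise floored at zero.
    """
    rng = config.rng(0)
    low, high = config.width_range
    widths = np.linspace(low, high, config.n_sites)
    if config.width_jitter > 0:
        widths = np.clip(widths + rng.normal(0, config.width_jitter, config.n_sites), low, high)
    frac = (widths - low) / (high - low)  # 0 at narrowest, 1 at widest
    slope = config.slope_range_deg[1] + frac * (
        config.slope_range_deg[0] - config.slope_range_deg[1]
    )
    slope = np.maximum(0.1, slope * np.exp(rng.normal(0, 0.5, config.n_sites)))
    grain = config.grain_range_mm[1] + frac * (
        config.grain_range_mm[0] - config.grain_range_mm[1]
    )
    grain = np.maximum(0.05, grain * np.exp(rng.normal(0, 0.5, config.n_sites)))
    avail = config.availability
    wrack = np.maximum(
        0.0,
        config.wrack_scale_g * avail.amph(widths) / max(avail.amph_amplitude, 1e-12)
        + rng.normal(0, config.wrack_noise_g, config.n_sites),
    )
    burrow = np.maximum(
        0.0,
        config.burrow_scale * avail.predator(widths) / max(avail.predator_amplitude, 1e-12)
        + rng.normal(0, 0.1 * config.burrow_scale, config.n_sites),
    )
    return pd.DataFrame(
        {
            "site": [f"S{i + 1:02d}" for i in range(config.n_sites)],
            "width_m": widths,
            "slope_deg": slope,
            "grain_mm": grain,
            "wrack_g": wrack,
            "burrow_density": burrow,
        }
    )


def simulate_truth(sites: pd.DataFrame, config: ScenarioConfig) -> SyntheticTruth:
    """Derive true diet proportions and site-shifted source means.

    Raw availability scores from the three curves (negatives clipped to 0)
    are normalized to the diet simplex per site; a site where every score is
    zero falls back to the uniform diet (1/3, 1/3, 1/3).
    """
    if len(sites) == 0:
        raise ConfigError("sites table is empty")
    rng = config.rng(1)
    avail = config.availability
    w = sites["width_m"].to_numpy()
    scores = np.column_stack(
        [np.clip(avail.mole(w), 0, None), np.clip(avail.amph(w), 0, None), np.clip(avail.coq(w), 0, None)]
    )
    totals = scores.sum(axis=1)
    p = np.full_like(scores, 1.0 / 3.0)
    ok = totals > 0
    p[ok] = scores[ok] / totals[ok, None]
    diet = pd.DataFrame({"site": sites["site"].to_numpy()})
    for k, taxon in enumerate(bio.PREY_TAXA):
        diet[f"p_{taxon}"] = p[:, k]

    rows = []
    for site in sites["site"]:
        for taxon in bio.PREY_TAXA:
            base_c, base_n = config.source_mean_bases[taxon]
            rows.append(
                {
                    "site": site,
                    "taxon": taxon,
                    "d13C": base_c + rng.normal(0, config.site_shift_sd),
                    "d15N": base_n + rng.normal(0, config.site_shift_sd),
                }
            )
    return SyntheticTruth(
        diet=diet,
        source_means=pd.DataFrame(rows),
        source_sd=config.source_sd,
        tef=config.tef_true,
        residual_sd=config.residual_sd,
    )


def simulate_isotopes(truth: SyntheticTruth, config: ScenarioConfig) -> pd.DataFrame:
    """Draw source replicates, consumer signatures and wrack components.

    Returns the three isotope tables ``(signatures, consumers,
    wrack_components)``; :func:`simulate_scenario` bundles them with the
    site table and truth ledger. Consumer draws follow the mixing model's
    closed-form forward distribution, so with all SDs zero a consumer equals
    the proportion-weighted TEF-corrected source mean exactly.
    """
    rng = config.rng(2)
    tef_mean, tef_sd = truth.tef
    sig_rows, cons_rows, wrack_rows = [], [], []
    sites = list(truth.diet["site"])
    missing = set(sites[: config.n_missing_amphipod_sites])

    sm = truth.source_means.set_index(["site", "taxon"])
    for site in sites:
        p = truth.diet_vector(site)
        means = {t: (sm.loc[(site, t), "d13C"], sm.loc[(site, t), "d15N"]) for t in bio.PREY_TAXA}

        # source replicates (withheld for amphipods at 'missing' sites)
        for taxon in bio.PREY_TAXA:
            if taxon == "amphipod" and site in missing:
                continue
            n_rep = int(rng.integers(config.n_source_reps[0], config.n_source_reps[1] + 1))
            for r in range(n_rep):
                sig_rows.append(
                    {
                        "site": site,
                        "taxon": taxon,
                        "replicate_id": f"{taxon[:4]}{r + 1}",
                        "d13C": rng.normal(means[taxon][0], config.source_sd),
                        "d15N": rng.normal(means[taxon][1], config.source_sd),
                    }
                )

        # consumers from the forward mixing distribution
        mu_c = float(sum(p[k] * means[t][0] for k, t in enumerate(bio.PREY_TAXA)))
        mu_n = float(sum(p[k] * (means[t][1] + tef_mean) for k, t in enumerate(bio.PREY_TAXA)))
        var_c = float(np.sum(p**2) * config.source_sd**2 + truth.residual_sd[0] ** 2)
        var_n = float(
            np.sum(p**2) * (config.source_sd**2 + tef_sd**2) + truth.residual_sd[1] ** 2
        )
        n_cons = int(rng.integers(config.n_consumers[0], config.n_consumers[1] + 1))
        for c in range(n_cons):
            cons_rows.append(
                {
                    "site": site,
                    "crab_id": f"crab{c + 1}",
                    "d13C": rng.normal(mu_c, math.sqrt(var_c)),
                    "d15N": rng.normal(mu_n, math.sqrt(var_n)),
                }
            )

        # wrack components whose proportional mixture inverts the nitrogen
        # calibration: mixture d15N = (amph d15N - b) / a, mixture d13C = amph d13C
        a, b = config.wrack_calibration
        target_n = (means["amphipod"][1] - b) / a + rng.normal(0, 0.2)
        target_c = means["amphipod"][0] + rng.normal(0, 0.2)
        off = abs(rng.normal(1.0, 0.3))
        props = (0.6, 0.4)
        # offsets chosen so the weighted mean equals the target exactly
        offs = (off, -props[0] * off / props[1])
        for i, (pr, o) in enumerate(zip(props, offs)):
            wrack_rows.append(
                {
                    "site": site,
                    "component": f"wrack{i + 1}",
                    "dry_mass_prop": pr,
                    "d13C": target_c + 0.5 * o,
                    "d15N": target_n + o,
                }
            )

    signatures = pd.DataFrame(sig_rows, columns=bio.SIGNATURES_COLUMNS)
    consumers = pd.DataFrame(cons_rows, columns=bio.CONSUMERS_COLUMNS)
    wrack = pd.DataFrame(wrack_rows, columns=bio.WRACK_COLUMNS)
    return signatures, consumers, wrack


def simulate_scenario(config: ScenarioConfig) -> SyntheticDataset:
    """Run the full forward simulation: sites -> truth -> isotope tables."""
    sites = simulate_sites(config)
    truth = simulate_truth(sites, config)
    signatures, consumers, wrack = simulate_isotopes(truth, config)
    return SyntheticDataset(
        sites=sites,
        signatures=signatures,
        consumers=consumers,
        wrack_components=wrack,
        truth=truth,
    )
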