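"""Bayesian multi-source, multi-isotope diet mixing for single consumers.

The model expresses one consumer's isotope signature as a proportion-
weighted mixture of TEF-corrected source signatures. For diet proportions
p on the simplex, source means s_jk and SDs sigma_jk, enrichment means
c_jk and SDs tau_jk (isotope j, source k), and per-isotope residual SD
epsilon_j, each observed delta_j is modelled as

    delta_j ~ Normal( sum_k p_k (s_jk + c_jk),
                      sum_k p_k^2 (sigma_jk^2 + tau_jk^2) + epsilon_j^2 )

with a Dirichlet(alpha) prior on p (all-ones by default) and independent
Uniform(0, bound) priors on the residual SDs. This is the classical
"single target organism per group" formulation: every individual consumer
gets its own posterior over the diet simplex, which can then be averaged
within a site.

Sampling uses component-wise random-walk Metropolis on the additive-log-
ratio transform of p and the log residual SDs, with proposal-scale
adaptation during burn-in targeting a 20-50% acceptance rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PREY_TAXA, DataError, SignatureSummary
from .tef import TEFSpec

__all__ = [
    "MixingModelSpec",
    "MCMCConfig",
    "DietPosterior",
    "log_posterior",
    "sample_posterior",
    "summarize_diet",
    "individual_diet_table",
]

logger = logging.getLogger(__name__)

#: Variance floor: any source/TEF SD of exactly 0 is replaced by this (‰)
#: inside the likelihood so the posterior stays proper on degenerate inputs.
SD_FLOOR = 0.01

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MixingModelSpec:
    """Sources, enrichment and priors for one mixing problem.

    Arrays are (n_isotopes, n_sources); the default problem is two isotopes
    (C, N) by three sources. Carbon enrichment rows are zeros.
    """

    source_means: np.ndarray
    source_sds: np.ndarray
    tef_means: np.ndarray
    tef_sds: np.ndarray
    alpha: np.ndarray | None = None  # Dirichlet concentration, default all-ones
    resid_sd_bound: float = 20.0
    source_labels: tuple[str, ...] = PREY_TAXA
    isotope_labels: tuple[str, ...] = ("d13C", "d15N")

    def __post_init__(self) -> None:
        shape = np.asarray(self.source_means).shape
        for name in ("source_sds", "tef_means", "tef_sds"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise DataError(f"{name} shape {getattr(self, name)} != source_means shape {shape}")
        if np.any(np.asarray(self.source_sds) < 0) or np.any(np.asarray(self.tef_sds) < 0):
            raise DataError("source/TEF SDs must be >= 0")
        if self.alpha is None:
            object.__setattr__(self, "alpha", np.ones(shape[1]))
        if np.any(np.asarray(self.alpha) <= 0):
            raise DataError("Dirichlet concentration must be positive")
        if self.resid_sd_bound <= 0:
            raise DataError("residual-SD prior bound must be positive")

    @property
    def n_sources(self) -> int:
        return np.asarray(self.source_means).shape[1]

    @property
    def n_isotopes(self) -> int:
        return np.asarray(self.source_means).shape[0]

    @classmethod
    def from_summaries(
        cls,
        source_summaries: Mapping[str, SignatureSummary],
        tef: TEFSpec,
        alpha: np.ndarray | None = None,
        resid_sd_bound: float = 20.0,
    ) -> "MixingModelSpec":
        """Build the three-source, two-isotope spec from site summaries.

        The nitrogen TEF (mean, SD) applies to every source; carbon
        enrichment is zero. Missing SDs (n = 1 summaries) fall back to the
        likelihood floor.
        """
        means, sds = [], []
        for taxon in PREY_TAXA:
            s = source_summaries[taxon]
            means.append([s.mean_d13C, s.mean_d15N])
            sds.append(
                [
                    SD_FLOOR if s.sd_d13C is None else s.sd_d13C,
                    SD_FLOOR if s.sd_d15N is None else s.sd_d15N,
                ]
            )
        k = len(PREY_TAXA)
        return cls(
            source_means=np.asarray(means, float).T,
            source_sds=np.asarray(sds, float).T,
            tef_means=np.array([[tef.carbon_mean] * k, [tef.nitrogen_mean] * k]),
            tef_sds=np.array([[tef.carbon_sd] * k, [tef.nitrogen_sd] * k]),
            alpha=alpha,
            resid_sd_bound=resid_sd_bound,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Run schedule and proposal settings for the Metropolis sampler."""

    iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 15
    seed: int = 0
    proposal_scale: float = 0.5
    adapt: bool = True

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise DataError("require iterations > burn_in >= 0")
        if self.thin < 1:
            raise DataError("thin must be >= 1")
        if self.proposal_scale <= 0:
            raise DataError("proposal_scale must be positive")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class DietPosterior:
    """Retained posterior draws over the diet simplex for one consumer."""

    draws: np.ndarray  # (n_retained, n_sources), each row on the simplex
    resid_sd_draws: np.ndarray  # (n_retained, n_isotopes)
    consumer_id: str = ""
    site: str = ""
    source_labels: tuple[str, ...] = PREY_TAXA
    acceptance_rate: float = float("nan")

    @property
    def n_retained(self) -> int:
        return self.draws.shape[0]

    @property
    def mean_proportions(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(2, n_sources) array of lower/upper equal-tail interval bounds."""
        lo = (1.0 - level) / 2.0
        return np.quantile(self.draws, [lo, 1.0 - lo], axis=0)


def _dirichlet_logpdf(p: np.ndarray, alpha: np.ndarray) -> float:
    # handles boundary p_k = 0 when alpha_k = 1 (term vanishes)
    out = math.lgamma(float(alpha.sum())) - sum(math.lgamma(a) for a in alpha)
    for pk, ak in zip(p, alpha):
        if ak != 1.0:
            if pk <= 0:
                return -math.inf
            out += (ak - 1.0) * math.log(pk)
    return out


def log_posterior(
    p: Sequence[float],
    resid_sd: Sequence[float],
    consumer: Sequence[float],
    spec: MixingModelSpec,
    include_likelihood: bool = True,
) -> float:
    """Log posterior density at diet proportions ``p`` and residual SDs.

    ``consumer`` is the observed delta vector in the spec's isotope order.
    Raises on off-simplex ``p`` (tolerance 1e-6); returns -inf for residual
    SDs outside the Uniform(0, bound) prior support.
    """
    p = np.asarray(p, float)
    resid_sd = np.asarray(resid_sd, float)
    consumer = np.asarray(consumer, float)
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise DataError(f"p = {p} is not on the simplex")
    if np.any(resid_sd < 0) or np.any(resid_sd > spec.resid_sd_bound):
        return -math.inf

    lp = _dirichlet_logpdf(p, np.asarray(spec.alpha, float))
    lp += -spec.n_isotopes * math.log(spec.resid_sd_bound)  # uniform prior density
    if not include_likelihood:
        return lp

    means = np.asarray(spec.source_means, float) + np.asarray(spec.tef_means, float)
    w = np.maximum(np.asarray(spec.source_sds, float), SD_FLOOR) ** 2 + np.maximum(
        np.asarray(spec.tef_sds, float), 0.0
    ) ** 2
    # tef sds of exactly zero are legitimate (carbon); only the summed
    # per-source variance needs a floor
    w = np.maximum(w, SD_FLOOR**2)
    for j in range(spec.n_isotopes):
        mu = float(np.dot(p, means[j]))
        var = float(np.dot(p**2, w[j])) + float(resid_sd[j]) ** 2
        if var <= 0:
            return -math.inf
        lp += -0.5 * (_LOG_2PI + math.log(var) + (consumer[j] - mu) ** 2 / var)
    return lp


def _alr_inverse(z: np.ndarray) -> np.ndarray:
    """Map additive-log-ratio coordinates (K-1,) to the open simplex (K,)."""
    ez = np.exp(z - max(0.0, z.max(initial=0.0)))  # guard overflow
    denom = math.exp(-max(0.0, z.max(initial=0.0))) + ez.sum()
    p = np.empty(len(z) + 1)
    p[:-1] = ez / denom
    p[-1] = math.exp(-max(0.0, z.max(initial=0.0))) / denom
    return p


def sample_posterior(
    consumer: Sequence[float],
    spec: MixingModelSpec,
    mcmc: MCMCConfig | None = None,
    fixed_resid_sd: Sequence[float] | None = None,
    prior_only: bool = False,
    consumer_id: str = "",
    site: str = "",
) -> DietPosterior:
    """Draw from the diet posterior by component-wise random-walk Metropolis.

    The chain moves on the additive-log-ratio transform of p (K-1 free
    coordinates) and, unless ``fixed_resid_sd`` is given, on the log
    residual SDs. Proposal scales adapt during burn-in toward a 20-50%
    acceptance rate and are then frozen. Identical seeds give identical
    draws.

    ``prior_only`` disables the likelihood (prior-recovery diagnostics).
    """
    mcmc = mcmc or MCMCConfig()
    consumer = np.asarray(consumer, float)
    nk, nj = spec.n_sources, spec.n_isotopes
    rng = np.random.default_rng(mcmc.seed)

    mix_means = (
        np.asarray(spec.source_means, float) + np.asarray(spec.tef_means, float)
    ).tolist()
    w = np.maximum(
        np.maximum(np.asarray(spec.source_sds, float), SD_FLOOR) ** 2
        + np.asarray(spec.tef_sds, float) ** 2,
        SD_FLOOR**2,
    ).tolist()
    alpha = [float(a) for a in np.asarray(spec.alpha, float)]
    bound = float(spec.resid_sd_bound)
    log_bound = math.log(bound)
    fixed = None if fixed_resid_sd is None else [float(s) for s in fixed_resid_sd]
    if fixed is not None and any(s < 0 or s > bound for s in fixed):
        raise RuntimeError(
            f"non-finite posterior at initialization: fixed residual SDs {fixed} "
            f"outside the Uniform(0, {bound}) prior support"
        )
    obs = [float(v) for v in consumer]
    # Dirichlet(alpha) normalizer; the (alpha_k - 1) log p_k prior term and
    # the ALR-Jacobian log p_k term combine into alpha_k * log p_k
    dir_const = math.lgamma(sum(alpha)) - sum(math.lgamma(a) for a in alpha)

    n_z = nk - 1
    n_free = n_z + (0 if fixed is not None else nj)
    exp, log = math.exp, math.log

    def unconstrained_logpost(u: list[float]) -> float:
        m = 0.0
        for i in range(n_z):
            if u[i] > m:
                m = u[i]
        ez = [exp(u[i] - m) for i in range(n_z)]
        last = exp(-m)
        denom = last + sum(ez)
        p = [e / denom for e in ez]
        p.append(last / denom)

        if fixed is not None:
            sd = fixed
            jac_sd = 0.0
        else:
            sd = []
            jac_sd = 0.0
            for i in range(n_z, n_free):
                s = exp(u[i])
                if s > bound:
                    return -math.inf
                sd.append(s)
                jac_sd += u[i]  # d(sd)/d(log sd) Jacobian

        lp = dir_const - nj * log_bound + jac_sd
        for k in range(nk):
            lp += alpha[k] * log(p[k])
        if not prior_only:
            for j in range(nj):
                mj, wj = mix_means[j], w[j]
                mu = 0.0
                var = sd[j] * sd[j]
                for k in range(nk):
                    mu += p[k] * mj[k]
                    var += p[k] * p[k] * wj[k]
                d = obs[j] - mu
                lp += -0.5 * (_LOG_2PI + log(var) + d * d / var)
        return lp

    # initialization: uniform diet, residual SD 1 ‰
    u = [0.0] * n_free
    cur_lp = unconstrained_logpost(u)
    if not math.isfinite(cur_lp):
        raise RuntimeError(
            "non-finite posterior at initialization; check source/TEF SDs "
            f"(values below the {SD_FLOOR} ‰ floor are raised automatically)"
        )

    scales = np.full(n_free, mcmc.proposal_scale)
    acc = np.zeros(n_free, int)
    win_acc = np.zeros(n_free, int)
    n_total = 0
    window = 100

    retained_p = np.empty((mcmc.n_retained, nk))
    retained_sd = np.empty((mcmc.n_retained, nj))
    r = 0

    normals = None
    uniforms = None
    for it in range(1, mcmc.iterations + 1):
        # draw randomness in blocks to keep the loop tight
        if (it - 1) % 512 == 0:
            normals = rng.standard_normal((512, n_free))
            uniforms = rng.random((512, n_free))
        row = (it - 1) % 512
        for i in range(n_free):
            old = u[i]
            u[i] = old + scales[i] * normals[row, i]
            new_lp = unconstrained_logpost(u)
            if new_lp - cur_lp > math.log(uniforms[row, i] + 1e-300):
                cur_lp = new_lp
                acc[i] += 1
                win_acc[i] += 1
            else:
                u[i] = old
        n_total += 1

        if mcmc.adapt and it <= mcmc.burn_in and it % window == 0:
            rate = win_acc / window
            scales *= np.where(rate > 0.5, 1.25, np.where(rate < 0.2, 0.8, 1.0))
            win_acc[:] = 0

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and r < len(retained_p):
            retained_p[r] = _alr_inverse(np.asarray(u[:n_z]))
            retained_sd[r] = fixed if fixed is not None else np.exp(u[n_z:])
            r += 1

    rate = float(acc.sum()) / (n_total * n_free)
    logger.info(
        "consumer %s site %s: %d retained draws, acceptance %.2f",
        consumer_id, site, r, rate,
    )
    return DietPosterior(
        draws=retained_p[:r],
        resid_sd_draws=retained_sd[:r],
        consumer_id=consumer_id,
        site=site,
        source_labels=spec.source_labels,
        acceptance_rate=rate,
    )


def individual_diet_table(posteriors: Sequence[DietPosterior], level: float = 0.95) -> pd.DataFrame:
    """One row per consumer: posterior mean proportions and credible bounds."""
    rows = []
    for post in posteriors:
        row: dict[str, object] = {"site": post.site, "crab_id": post.consumer_id}
        ci = post.credible_interval(level)
        for k, taxon in enumerate(post.source_labels):
            row[f"mean_p_{taxon}"] = post.mean_proportions[k]
            row[f"lo_p_{taxon}"] = ci[0, k]
            row[f"hi_p_{taxon}"] = ci[1, k]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_diet(posteriors: Sequence[DietPosterior]) -> pd.DataFrame:
    """Site-level mean diet proportions.

    Each consumer contributes its posterior-mean proportions; the site value
    is the arithmetic mean across consumers, so each site row again sums
    to 1. Empty site groups are skipped with a warning.
    """
    by_site: dict[str, list[np.ndarray]] = {}
    labels = posteriors[0].source_labels if posteriors else PREY_TAXA
    for post in posteriors:
        if post.n_retained == 0:
            logger.warning("empty posterior for %s/%s skipped", post.site, post.consumer_id)
            continue
        by_site.setdefault(post.site, []).append(post.mean_proportions)
    rows = []
    for site in sorted(by_site):
        means = np.mean(by_site[site], axis=0)
        row = {"site": site, "n_consumers": len(by_site[site])}
        for k, taxon in enumerate(labels):
            row[f"mean_p_{taxon}"] = means[k]
        rows.append(row)
    return pd.DataFrame(rows)
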