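"""Infer one consumer's diet with the Bayesian three-source mixing model.

Sources are TEF-corrected; the posterior over the diet simplex is sampled
by random-walk Metropolis on additive-log-ratio coordinates. The paper-
style schedule (100k iterations, 10k burn-in, thin 15) retains exactly
6000 draws; here we use a shorter schedule for speed.
"""

import numpy as np

from beachmix import MCMCConfig, MixingModelSpec, sample_posterior

spec = MixingModelSpec(
    source_means=np.array([[-12.0, -17.0, -22.0],   # d13C: mole, amph, coquina
                           [4.0, 10.0, 7.0]]),      # d15N
    source_sds=np.full((2, 3), 0.5),
    tef_means=np.array([[0.0] * 3, [2.3] * 3]),     # nitrogen enrichment only
    tef_sds=np.array([[0.0] * 3, [0.3] * 3]),
)

# a consumer whose signature implies roughly 60/25/15 mole/amph/coquina
p_true = np.array([0.6, 0.25, 0.15])
consumer = [
    float(p_true @ spec.source_means[0]),
    float(p_true @ (spec.source_means[1] + 2.3)),
]
post = sample_posterior(
    consumer, spec,
    MCMCConfig(iterations=20_000, burn_in=2_000, thin=15, seed=1),
    fixed_resid_sd=(0.0, 0.0),  # solo likelihood: process error only
)

print(f"Consumer signature: d13C {consumer[0]:.2f} ‰, d15N {consumer[1]:.2f} ‰")
print(f"Retained draws: {post.n_retained}  (acceptance rate {post.acceptance_rate:.2f})")
ci = post.credible_interval(0.95)
for k, taxon in enumerate(post.source_labels):
    print(f"  p({taxon:9s}) = {post.mean_proportions[k]:.3f} "
          f"[95% CI {ci[0, k]:.3f}, {ci[1, k]:.3f}]  (true {p_true[k]:.2f})")
print()
print("Posterior means recover the generating proportions; the credible "
      "intervals quantify what two tracers can say about a three-part diet.")
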