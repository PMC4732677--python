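"""End-to-end run: simulate a study, then summarize -> impute -> TEF ->
mix -> trophic position -> gradient models, all from CSV inputs.

Uses a reduced MCMC schedule so the whole run takes a few seconds.
Equivalent shell usage:

    beachmix simulate --seed 5 --n-sites 8 --out-dir data/
    beachmix run-all --sites data/sites.csv --signatures data/signatures.csv \
        --consumers data/consumers.csv --wrack data/wrack_components.csv \
        --out-dir out/ --iterations 5000 --burn-in 1000 --thin 5 --seed 5
"""

import tempfile
from pathlib import Path

from beachmix import MCMCConfig, PipelineConfig, ScenarioConfig, run_all, simulate_scenario

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    ds = simulate_scenario(ScenarioConfig(n_sites=8, seed=5, n_missing_amphipod_sites=1))
    ds.write(data)

    result = run_all(PipelineConfig(
        sites_path=str(data / "sites.csv"),
        signatures_path=str(data / "signatures.csv"),
        consumers_path=str(data / "consumers.csv"),
        wrack_path=str(data / "wrack_components.csv"),
        out_dir=str(Path(tmp) / "out"),
        mcmc=MCMCConfig(iterations=5_000, burn_in=1_000, thin=5, seed=5),
        seed=5,
    ))

print("Per-site mean diet proportions (posterior means averaged over crabs):")
print(result.site_diets.round(3).to_string(index=False))
print()
print("Trophic positions:")
print(result.tp_table.round(3).to_string(index=False))
print()
imputed = result.summaries.query("imputed == 1")
print(f"Imputed amphipod sources: {len(imputed)} (site {', '.join(imputed['site'])})")
print()
print("One site lacked amphipod tissue; its source was imputed from wrack "
      "before mixing. Diet shifts from mole crab to coquina across the "
      "gradient while trophic position stays near one enrichment step "
      "above the prey baseline.")
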