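"""Forward-simulate a 16-site beach gradient with known diet truth.

Generates the site table (width, slope, grain size, wrack, burrow density),
true diet proportions from the availability curves, and the isotope tables
(source replicates, consumer signatures, wrack components).
"""

from beachmix import ScenarioConfig, simulate_scenario

ds = simulate_scenario(ScenarioConfig(n_sites=16, seed=42))

print("Site physical records (first 4 of 16):")
print(ds.sites.head(4).round(2).to_string(index=False))
print()
print("True diet proportions along the gradient (first 4 sites):")
print(ds.truth.diet.head(4).round(3).to_string(index=False))
print()
print(f"{len(ds.signatures)} source replicate signatures, "
      f"{len(ds.consumers)} individual consumers.")
print()
print("Narrow sites are steep/coarse with mole-crab-dominated diets; wide "
      "sites are flat/fine and coquina-dominated; amphipods peak near 40 m "
      "where wrack accumulates. These proportions are the ground truth that "
      "the mixing model is later asked to recover.")
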