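"""Generate a complete synthetic study with known ground truth.

Builds a Yule species tree, places independent losses of mycorrhizal
competence, evolves gene-family presence/absence with trait-coupled loss
and writes every pipeline input plus a run manifest.
"""

from pathlib import Path

from amtoolkit.simulate import SimulationConfig, write_simulated_inputs

config = SimulationConfig(
    n_species=30, n_trait_losses=4, n_families=200, n_genes=500, seed=42
).validate()
paths = write_simulated_inputs(Path("scratch_sim"), config)

for name, path in paths.items():
    print(f"{name:16s} {path}")
print()
print(
    f"Simulated {config.n_families} gene families over {config.n_species} "
    f"species with {config.n_trait_losses} independent trait losses; "
    "symbiosis-linked families lose their gene "
    f"{config.coupled_loss_multiplier:.0f}x faster in nonhost lineages. "
    "The manifest records every parameter, and family_truth.tsv / "
    "gene_truth.tsv hold the ground truth the inference stages should recover."
)
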