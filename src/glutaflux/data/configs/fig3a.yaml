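# Bifido-shunt augmentation: acetyl-CoA ceiling per glucose without and with
# the phosphoketolase reactions (2 vs 3 mol/mol).
run_id: fig3a
model:
  source: core
  genotype: wild_type
simulation:
  substrate_uptake_max: 4.67
  biomass_fraction: 0.2
  bifido_probe: DM_accoa
stages: [bifido_compare]
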