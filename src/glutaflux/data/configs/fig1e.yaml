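# Aconitase attenuation sweep on the engineered leucine-producer background:
# relative ACN flux capped 1.0 -> 0.1 against the native (growth) control.
run_id: fig1e
model:
  source: core
  genotype: leucine_producer
simulation:
  substrate_uptake_max: 4.67
  biomass_fraction: 0.2
  product_exchange: EX_leu__L_e
  sweep_target: ACONT
  sweep_fractions: [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1]
stages: [sweep]
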