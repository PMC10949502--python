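# Essentiality classification and regulation modes for the leucine producer
# design on the wild-type core model (20% biomass floor, leucine objective).
run_id: fig1a
model:
  source: core
  genotype: wild_type
simulation:
  substrate_uptake_max: 4.67
  biomass_fraction: 0.2
  product_exchange: EX_leu__L_e
stages: [build_model, classify, recommend, yields]
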