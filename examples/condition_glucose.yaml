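# Standard single-carbon batch condition for a genome-scale reconstruction
# (BiGG-style metabolite ids): limited D-glucose, everything inorganic in
# excess.  The uptake caps below are PLACEHOLDERS — maximal uptake rates are
# reconstruction- and study-specific and should be replaced with the values
# appropriate to your model before quantitative use.
carbon_source: glc__D_e
initial_concentration: 10.0     # mmol/L
initial_biomass: 0.003          # gDW/L
time_step: 0.1                  # h
max_time: 100.0                 # h
in_excess:
  - o2_e
  - nh4_e
  - pi_e
  - so4_e
  - h2o_e
  - h_e
  - k_e
  - na1_e
  - fe2_e
uptake_caps:
  glc__D_e: 10.0                # mmol/gDW/h, placeholder
  o2_e: 20.0                    # placeholder
condition_id: glucose
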