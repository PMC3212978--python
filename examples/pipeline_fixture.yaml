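# Desk-scale end-to-end run on the built-in overflow cross-feeding network.
# Usage: crossfeed pipeline examples/pipeline_fixture.yaml
model_path: "fixture:crossfeed"
condition:
  carbon_source: glc_e
  initial_concentration: 10.0   # mmol/L
  initial_biomass: 0.003        # gDW/L
  time_step: 0.1                # h
  max_time: 100.0               # h
  uptake_caps:
    glc_e: 10.0                 # mmol/gDW/h
    byp_e: 10.0
  condition_id: glc_fixture
binarize_threshold: 0.6
centrality_cutoff: 0.9
max_communities: 10
output_dir: crossfeed_out
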