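# Demo pipeline run: simulate a sustained-response condition, call
# responders, and quantify one rendered tissue section.
#   ktrq report --config examples/demo_config.yaml
stages: [traces, tissue]
seed: 7
out_dir: ktrq_demo_run
sim:
  response_class: 3
  n_cells: 200
  dose: 100.0
tissue_sim:
  n_tumors: 8
  image_shape: [512, 512]
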