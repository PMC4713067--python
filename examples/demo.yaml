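# Demo pipeline configuration: full synthetic generate -> analyze -> summarize.
# Run:  gcmotility all --config examples/demo.yaml --outdir demo_out --seed 1
seed: 1
outdir: demo_out
motility:
  n_cycles: 3
bead:
  thermal_sd_nm: 6.0
  event_schedule:
    - {start_s: 2.0, direction: "+x", speed_nm_s: 14.0, duration_s: 10.0}
filopodia:
  n: 3
  rate_um_s: 0.10
  max_len_um: 3.36
  frame_interval_s: 2.0
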