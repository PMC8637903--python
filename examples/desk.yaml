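# Desk-scale end-to-end run: two-tube phantom, 32 channels, 150 frames.
seed: 1
output_dir: tuvi_output
phantom:
  preset: two_tube
  flow_speed_mm_s: 30
  concentration_per_mm: 0.5
acquisition:
  n_channels: 32
  n_frames: 150
stf:
  low_rank_cut: auto
track:
  n_iterations: 10000
  burn_in: 2000
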