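# Example study configuration for `engagesense analyze --config ...`.
mode: synthetic          # or csv-dir (then set input_dir)
threshold: calibrate     # or a numeric activation threshold in mV
clarity: 0.05            # relative-change clarity for sign extraction
reactive_durations: [10.0, 30.0]
min_mission3: 4
seed: 1
session:
  n_participants: 26
  event_rate: 0.6        # events per minute of Gameplay
calibration:
  n_participants: 6
  dwell: 10.0
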