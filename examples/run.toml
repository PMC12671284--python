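# Example run configuration. Any omitted key falls back to its default;
# unknown keys are rejected. The top-level seed drives all randomness.
seed = 1

[device]
orientation = "horizontal"
theta_min_deg = 0.0          # working range: wrist neutral ...
theta_max_deg = 30.0         # ... to 30 degrees
force_direction = "off"      # "toward_min" | "toward_max" | "off"
force_magnitude_Nmm = 0.0
inertia_kgmm2 = 50.0
damping_Nmm_s_per_rad = 5.0

[game]
session_duration_s = 60.0
event_duration_s = 2.0
paddle_width_pct = 10.0
target_width_pct = 5.0
distractors_enabled = false
frame_rate_hz = 120.0

[player]
preset = "stroke_moderate"   # or give explicit PlayerModel fields
tremor_sd_pct = 1.0          # fields here override the preset

[metrics]
onset_threshold_pct = 2.0
min_hold_s = 0.05
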