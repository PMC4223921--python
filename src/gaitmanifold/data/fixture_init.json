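{
 "hat_state": [
  0.02790476419671539,
  119.88858302044207,
  1.1011721205175675,
  -0.15976122834003847,
  0.9935621712256039,
  0.07801820280678086
 ],
 "dt": 1e-05,
 "seed": 0,
 "template": {
  "T": 1.135,
  "speed": 0.9,
  "hip_height": 0.8,
  "bob": 0.012,
  "phi_ff": 0.08,
  "phi_ho": 0.4,
  "phi_to": 0.6,
  "pitch_hs": 0.15,
  "pitch_po": 0.32,
  "clearance": 0.135,
  "phi_peak": 0.78,
  "heel_slope": -0.12,
  "anchor_frac": 0.3,
  "foot_lead": 0.0,
  "settle": 0.012,
  "trunk_lean": 0.0
 },
 "diagnostics": {
  "strobo_residual": 2.544366715040708e-11,
  "ds_episode_fraction": 0.17199559471365639,
  "stride_m": 1.0011288279306,
  "speed_m_s": 0.8820518307758591,
  "cycles_walked": 120
 }
}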