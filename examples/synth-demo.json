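{
 "n_trials_per_stimulus": 12,
 "stimulus_duration_s": 2.0,
 "motifs_per_song": 2,
 "inter_trial_interval_s": 5.0,
 "contexts": [
  "solitary",
  "social"
 ],
 "stimuli": [
  "BOS",
  "BOS_REV",
  "CON",
  "WN"
 ],
 "units": [
  {
   "unit_id": "u000",
   "baseline_rate_hz": {
    "solitary": 8.711453858556915,
    "social": 3.584528853049953
   },
   "evoked_gain": {
    "BOS:solitary": 3.0,
    "BOS:social": 2.0,
    "BOS_REV:solitary": 1.5,
    "BOS_REV:social": 1.25,
    "CON:solitary": 1.5,
    "CON:social": 1.25,
    "WN:solitary": 1.5,
    "WN:social": 1.25
   },
   "adaptation_floor": 1.0,
   "adaptation_tau_trials": 10.0,
   "offset_gain": {
    "solitary": 1.5,
    "social": 1.5
   },
   "waveform_width_ms": 0.21131295757067112,
   "waveform_sampling_hz": 30000.0,
   "unit_class": null,
   "refractory_s": 0.0
  },
  {
   "unit_id": "u001",
   "baseline_rate_hz": {
    "solitary": 11.687003627491498,
    "social": 16.63336073522161
   },
   "evoked_gain": {
    "BOS:solitary": 3.0,
    "BOS:social": 2.0,
    "BOS_REV:solitary": 1.5,
    "BOS_REV:social": 1.25,
    "CON:solitary": 1.5,
    "CON:social": 1.25,
    "WN:solitary": 1.5,
    "WN:social": 1.25
   },
   "adaptation_floor": 1.0,
   "adaptation_tau_trials": 10.0,
   "offset_gain": {
    "solitary": 1.5,
    "social": 1.5
   },
   "waveform_width_ms": 0.7446571266478867,
   "waveform_sampling_hz": 30000.0,
   "unit_class": null,
   "refractory_s": 0.0
  },
  {
   "unit_id": "u002",
   "baseline_rate_hz": {
    "solitary": 8.039739734264595,
    "social": 90.04537498608835
   },
   "evoked_gain": {
    "BOS:solitary": 3.0,
    "BOS:social": 2.0,
    "BOS_REV:solitary": 1.5,
    "BOS_REV:social": 1.25,
    "CON:solitary": 1.5,
    "CON:social": 1.25,
    "WN:solitary": 1.5,
    "WN:social": 1.25
   },
   "adaptation_floor": 1.0,
   "adaptation_tau_trials": 10.0,
   "offset_gain": {
    "solitary": 1.5,
    "social": 1.5
   },
   "waveform_width_ms": 0.35556192634036243,
   "waveform_sampling_hz": 30000.0,
   "unit_class": null,
   "refractory_s": 0.0
  },
  {
   "unit_id": "u003",
   "baseline_rate_hz": {
    "solitary": 3.757575818427813,
    "social": 13.3479454657166
   },
   "evoked_gain": {
    "BOS:solitary": 3.0,
    "BOS:social": 2.0,
    "BOS_REV:solitary": 1.5,
    "BOS_REV:social": 1.25,
    "CON:solitary": 1.5,
    "CON:social": 1.25,
    "WN:solitary": 1.5,
    "WN:social": 1.25
   },
   "adaptation_floor": 1.0,
   "adaptation_tau_trials": 10.0,
   "offset_gain": {
    "solitary": 1.5,
    "social": 1.5
   },
   "waveform_width_ms": 0.6051658865653156,
   "waveform_sampling_hz": 30000.0,
   "unit_class": null,
   "refractory_s": 0.0
  },
  {
   "unit_id": "u004",
   "baseline_rate_hz": {
    "solitary": 6.577170841360116,
    "social": 5.098318267280457
   },
   "evoked_gain": {
    "BOS:solitary": 3.0,
    "BOS:social": 2.0,
    "BOS_REV:solitary": 1.5,
    "BOS_REV:social": 1.25,
    "CON:solitary": 1.5,
    "CON:social": 1.25,
    "WN:solitary": 1.5,
    "WN:social": 1.25
   },
   "adaptation_floor": 1.0,
   "adaptation_tau_trials": 10.0,
   "offset_gain": {
    "solitary": 1.5,
    "social": 1.5
   },
   "waveform_width_ms": 0.23896772656687074,
   "waveform_sampling_hz": 30000.0,
   "unit_class": null,
   "refractory_s": 0.0
  },
  {
   "unit_id": "u005",
   "baseline_rate_hz": {
    "solitary": 9.521930986520605,
    "social": 11.693334754517837
   },
   "evoked_gain": {
    "BOS:solitary": 3.0,
    "BOS:social": 2.0,
    "BOS_REV:solitary": 1.5,
    "BOS_REV:social": 1.25,
    "CON:solitary": 1.5,
    "CON:social": 1.25,
    "WN:solitary": 1.5,
    "WN:social": 1.25
   },
   "adaptation_floor": 1.0,
   "adaptation_tau_trials": 10.0,
   "offset_gain": {
    "solitary": 1.5,
    "social": 1.5
   },
   "waveform_width_ms": 0.45025011708100987,
   "waveform_sampling_hz": 30000.0,
   "unit_class": null,
   "refractory_s": 0.0
  }
 ],
 "lfp": {
  "n_channels": 4,
  "sampling_rate_hz": 500.0,
  "noise_spectrum_exponent": 1.0,
  "line_hz": 60.0,
  "line_amplitude": 0.5,
  "band_effects": [
   [
    "CON",
    "solitary",
    10.0,
    4.0,
    4.0
   ]
  ],
  "band_base_amplitude": 1.0
 },
 "seed": 42,
 "lead_in_s": 5.0
}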