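{
 "out_dir": "demo_output",
 "session_dir": null,
 "synth_config": "examples/synth-demo.json",
 "seed": 42,
 "ssa_threshold": 0.6,
 "width_threshold_ms": 0.43,
 "alpha_responsive": 0.05,
 "alpha_compare": 0.05,
 "alpha_lfp": 0.01,
 "n_perm": 500,
 "lfp_baseline": "before",
 "fmax_hz": 50.0,
 "ctx1": "solitary",
 "ctx2": "social",
 "sqrt_denominator": true
}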