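# ephys-context

Analysis pipeline for context-dependent auditory responses in awake songbird
electrophysiology. Given a recording session — a stimulus-epoch table
(playback trials of BOS / BOS_REV / CON / WN in solitary, social or directed
contexts), per-unit spike times, mean spike waveforms, and a multichannel
LFP signal — it computes:

- **Per-unit spike metrics**: trial-paired baseline-normalized Z,
  response strength (RS), d′ stimulus selectivity, stimulus-specific
  adaptation (SSA) ratio, offset ratio / offset Z, and paired-t
  responsiveness, with the motif-level FR / trial-baseline pairing
  conventions (1 s baseline window starting 2 s before onset; 1 s offset
  window after the last motif; half-open intervals throughout).
- **Unit classification**: broad- vs narrow-spiking from trough-to-peak
  waveform width (BS > 0.43 ms, NS otherwise).
- **LFP spectral statistics**: 60 Hz notch → common average reference →
  before/during/after envelopes (2 s, 0.5 s buffer) → channel-averaged
  Welch PSD on 0–50 Hz → per-frequency trial-label permutation tests
  (2,500 permutations, sign-directed one-sided p) for stimulus-vs-baseline
  and solitary-vs-social contrasts.
- **Population comparisons**: paired Wilcoxon signed-rank tests across
  contexts, pooled and per stimulus, with in-repo Holm–Bonferroni
  correction; units are filtered to responsive AND SSA > 0.6 for at least
  one stimulus.
- **Synthetic sessions**: a first-class generator (`synth`) producing
  block-randomized schedules, inhomogeneous-Poisson units with programmed
  baseline/evoked/adaptation/offset structure, width-controlled biphasic
  waveforms, and 1/f LFP with line noise and stimulus-locked band power —
  so every stage is testable with known ground truth.

## CLI

The `ephys-context` entry point exposes one subcommand per stage:

```bash
# generate a synthetic session directory (epochs.csv, spikes.csv,
# waveforms.csv, lfp.bin + lfp.json, session.json)
ephys-context synth --config examples/synth-demo.json --out session/

# per-unit metrics (+ companion d' table)
ephys-context metrics --session session/ --ssa-threshold 0.6 --alpha 0.05 \
    --out metrics.csv

# LFP permutation tests (baseline: before | after | before_vs_after)
ephys-context lfp --session session/ --baseline before --n-perm 2500 \
    --alpha 0.01 --fmax 50 --seed 0 --out lfp_results.csv

# solitary-vs-social Wilcoxon comparisons with Holm correction
ephys-context compare --metrics metrics.csv --ctx1 solitary --ctx2 social \
    --alpha 0.05 --out comparisons.csv

# everything at once, from a single JSON run-config
ephys-context run --config examples/run-demo.json
ephys-context report --run-dir demo_output/
```

All thresholds default to the study's values (SSA 0.6, width 0.43 ms,
responsiveness α = 0.05, LFP α = 0.01, 2,500 permutations) and every run is
fully deterministic under its seed: rerunning with the same config produces
byte-identical outputs. `--no-sqrt-denominator` on `metrics` reproduces the
Z and d′ formulas exactly as typeset (without the square root) instead of
the standard definitions.

A note on the LFP decision rule: the reported p-value is the one-sided
permutation tail in the direction of the observed statistic (uniform on
[0, 0.5] under the null), so the `significant` flag compares it to α/2 to
keep the test's actual size at α.

## Layout

```
src/ephys_context/
  session_model.py   # domain types + on-disk formats (CSV / binary LFP)
  synth.py           # synthetic session generator
  spike_metrics.py   # Z, RS, d', SSA, offset responses, BS/NS, filters
  lfp_analysis.py    # notch + CAR, envelopes, Welch PSD, permutation tests
  group_stats.py     # Wilcoxon comparisons, Holm-Bonferroni
  pipeline.py        # run_all orchestration + run log
  cli.py             # click CLI
tests/               # unit + property + acceptance suites (oracles.py holds
                     # the independent brute-force reference implementations)
```
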