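# Demo run: synthetic quarter with agent-specific infection multipliers.
scenario: demo
n_cases: 20000
seed: 0
out_dir: results/demo
alpha: 0.05
shrinkage: true
interval: gamma
correction: haldane
meta_method: auto
min_cases: 1
keep_intermediates: false
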