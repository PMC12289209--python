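# demo pipeline configuration: 20-minute synthetic deployment
seed: 1
out_dir: scratch/demo
mass_kg: 1.14
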