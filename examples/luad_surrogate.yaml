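# Overrides for the built-in two-step LUAD surrogate calibration plan.
# Run with:  stepcal calibrate --plan examples/luad_surrogate.yaml --seed 7
data_seed: 7            # seed of the synthetic dataset generator
repeats: 3              # CMA-ES runs per step (best-of-N kept)
step2_population: 20
step2_max_generations: 500
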