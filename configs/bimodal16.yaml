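# 16-state bimodal sweep preset.  Run with:
#   qbnoise sweep --config configs/bimodal16.yaml --model bimodal16 --out results/bimodal16
# or from Python:
#   run_sweep(SweepConfig.from_yaml("configs/bimodal16.yaml"),
#             model_factory=bimodal_factory())
gamma_list: [10.0, 20.0]
beta_grid: [1.0, 3.76, 14.1, 53.2, 200.0]
n_reps: 10
photons_per_stream: 8000
tau: 43.3
qe: 1.0
curves: [photon_floor, delayed_optimal, if_deterministic, if_full_noise]
master_seed: 0
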