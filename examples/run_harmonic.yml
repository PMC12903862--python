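# Tethered-harmonic solvation leg (reduced units).
# Exact answer: dG = (3/2) kBT ln(k1/k0) = 2.0794 for k0=1, k1=4 at kBT=1.
system: {kind: harmonic, k0: 1.0, k1: 4.0}
thermo: {temperature: 1.0, kB: 1.0}
sampler:
  dt: 0.05
  friction: 1.0
  steps_per_iteration: 20
  n_iterations: 400
  equilibration_steps: 200
lambda_schedule: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
output_dir: leg_out
seed: 11
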