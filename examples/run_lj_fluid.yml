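# LJ test-particle decoupling: 1 solute in 32 solvent particles,
# reduced T* = 2.0, rho* = 0.3; dG approximates the excess chemical
# potential and can be cross-checked by Widom insertion.
system: {kind: lj_fluid, n_solvent: 32, density: 0.3, cutoff: 2.3}
thermo: {temperature: 2.0, kB: 1.0}
sampler:
  dt: 0.004
  friction: 1.0
  steps_per_iteration: 100
  n_iterations: 200
  equilibration_steps: 2000
lambda_schedule: {preset: default, K: 8}
output_dir: lj_out
seed: 3
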