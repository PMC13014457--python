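{
 "mu_coefs": [
  1.088223712622613,
  -0.17245783080688903
 ],
 "sigma_coefs": [
  0.29899622161322437,
  -1.348263158922208
 ],
 "n_sampled": 500,
 "rng_seed": 20,
 "size_range": [
  10,
  30
 ]
}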