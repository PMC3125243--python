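# Factorial metacommunity experiment: canonical competitor grid at reduced
# replication. The focal species keeps its defaults (16 genes, scale-free,
# mu 1e-4, rec 0.05).
sim:
  generations: 750
  canalization_gens: 20
  omega: 2.0
  lambda_: 1.5
  K: 200
  rates: [1.0e-3, 2.5e-4, 1.0e-4]

focal:
  d: 0.05

competitor:
  topology: scale_free

experiment:
  design:
    competitor_n: [16, 64, 256]
    competitor_mu: [1.0e-3, 1.0e-4, 1.0e-5]
    competitor_d: [0.01, 0.05, 0.1]
  replicates: 3
  master_seed: 1
  output_dir: results/metacommunity
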