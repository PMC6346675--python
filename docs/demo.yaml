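# Demonstration pipeline configuration: three remnant source herds found
# two new herds (one single-source, one mixed); the full pipeline then
# filters, infers admixture, and summarizes diversity, differentiation and
# isolation by distance.
seed: 11
stages: [simulate, filter, admix, stats, spatial, cohort]
simulate:
  n_sources: 3
  F: 0.07
  n_loci: 1500
  sample_size: 8
  mean_depth: 6
  generations: 6
  herd_size: 100
  ledger:
    - {source: S1, destination: D1, year: 1975, count: 15}
    - {source: S1, destination: D2, year: 1980, count: 12}
    - {source: S2, destination: D2, year: 1984, count: 12}
filter:
  one_per_contig: false
admix:
  k_range: [2, 3]
  n_iter: 4000
  burn_in: 1000
  thin: 10
spatial:
  n_perm: 999
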