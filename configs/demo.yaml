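# End-to-end demo configuration for `mucin pipeline`.
# All defaults mirror the core analysis parameters: ancestral copy number 5,
# gain/loss rates 0.5-2.0 per Myr, theta grid within 0.2-5.5, truncation
# bound 12 copies, 15-gene windows, 1% specificity quantile.
seed: 20160825

cds:
  species: [Human, Chimpanzee, Gorilla, Orangutan, Rhesus]
  burst: {Rhesus: 5}
  subs_per_unit: 1

genotypes: {}

phylo_cn:
  reps: 1000

coalescent:
  theta_grid: [0.2, 1.0, 5.5]
  reps: 200
  max_cn: 12

expression:
  n_genes: 600
  n_specific: 16
  cluster_size: 10
  cluster_start: 300
  fold_change: 5.0
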