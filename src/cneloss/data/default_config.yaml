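tree_newick: "(Zv9:0.35,(hipCom0:0.22,((fr3:0.09,gasAcu1:0.08):0.05,(oryLat2:0.1,oreNil2:0.09):0.04):0.06):0.12);"
pi: [0.3, 0.2, 0.2, 0.3]
exchangeabilities: [1.0, 2.0, 1.0, 1.0, 2.0, 1.0]
rho_conserved: 0.3
n_elements: 500
element_length_mean: 60.0
element_length_min: 40
element_length_max: 120
background_length: 200000
n_chromosomes: 1
loss_plan:
  hipCom0: 20
  fr3: 10
  gasAcu1: 10
  oryLat2: 10
gap_plan:
  hipCom0: 10
  fr3: 5
  gasAcu1: 5
  oryLat2: 5
n_genes: 10
gene_codons: 100
min_n_run: 10
seed: 42
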