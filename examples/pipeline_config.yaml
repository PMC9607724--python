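# Full pipeline on a simulated repertoire; see `bcrcoherence run --help`.
# To run on real data instead, replace `simulate` with:
#   airr_paths: [path/to/repertoire.airr.tsv]
#   germline_fasta: path/to/germline.fasta
outdir: scratch/pipeline_demo
seed: 1
n_permutations: 200
contingency_n_mc: 2000
junction_max_cells: 500
simulate:
  seed: 1
  n_donors: 4
  naive_per_donor: 300
  memory_per_donor: 300
  public:
    n_keys: 20
    donors_per_key: 4
    copies_per_donor: 2
    p_coherent: 0.8
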