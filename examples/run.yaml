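# Full pipeline configuration (desk-scale preset).
# Production-scale analyses raise n_seeds to 100000 and n_permutations to 4000.
seed: 0
omnibus:
  factor: 0.6        # threshold = factor x Otsu(H)
  n_bins: 256
  min_cluster: 20    # voxels (= 40 mm extent at 2 mm voxels)
  connectivity: 26
tracking:
  qa_threshold: 0.1  # overridden by the computed 0.6 x Otsu(QA) in `run`
  angular_threshold_deg: 60
  min_length: 10.0
  max_length: 400.0
  n_seeds: 5000
  seed: 0
designs:
  - mode: group_compare
    contrast: [EPT, TC]
    t_threshold: 2.0
    length_threshold: 40.0
    n_permutations: 200
    fdr_level: 0.05
    tip_rounds: 2
    seed: 0
constrain_by_pool: true
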