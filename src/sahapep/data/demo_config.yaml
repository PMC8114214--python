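# Small-scale demo configuration: three cell lines sharing a leucine
# anchor at p3 and hydrophobic C-terminal preferences, four replicates
# each, plus an allele universe with a planted F-pocket match and a
# three-group alpha-chain digest (one group present in only two of four
# replicates).
synthetic:
  seed: 7
  shared_fraction: 0.06
  n_source_proteins: 500
  neural_fraction: 0.1
  cell_lines:
    - name: fibroblasts
      n_unique_target: 2000
      n_replicates: 4
      detection_probability: 0.45
      length_distribution: {7: 0.05, 8: 0.26, 9: 0.22, 10: 0.15, 11: 0.11,
                            12: 0.08, 13: 0.06, 14: 0.04, 15: 0.03}
      motif_mixture:
        - weight: 1.0
          anchors:
            3: {L: 0.35}
            2: {Q: 0.25}
            omega: {L: 0.30, V: 0.15, F: 0.12, P: 0.08}
    - name: DFT1_IFNg
      n_unique_target: 1500
      n_replicates: 4
      detection_probability: 0.45
      length_distribution: {7: 0.05, 8: 0.22, 9: 0.26, 10: 0.15, 11: 0.11,
                            12: 0.08, 13: 0.06, 14: 0.04, 15: 0.03}
      motif_mixture:
        - weight: 1.0
          anchors:
            3: {L: 0.25}
            omega: {L: 0.30, V: 0.15, F: 0.12, P: 0.08}
    - name: DFT2
      n_unique_target: 800
      n_replicates: 4
      detection_probability: 0.45
      length_distribution: {7: 0.05, 8: 0.26, 9: 0.22, 10: 0.15, 11: 0.11,
                            12: 0.08, 13: 0.06, 14: 0.04, 15: 0.03}
      motif_mixture:
        - weight: 1.0
          anchors:
            3: {L: 0.35}
            1: {D: 0.22}
            omega: {L: 0.30, V: 0.15, F: 0.12, P: 0.08}
  allele_universe:
    n_db: 50
    seq_length: 182
    identity_baseline: 0.3
    planted_pocket: F
    adjacent_radius: 1
    n_paired_groups: 1
  digest:
    cell_line: fibroblasts
    n_replicates: 4
    n_peptides_per_replicate: 500
    group_abundances: {G0: 0.5, G1: 0.3, G2: 0.2}
    present_replicates: {G2: [1, 2]}
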