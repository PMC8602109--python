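# Demo study: synthetic two-subunit miniature (16 residues, 4 pseudo-atoms
# each, chains A/B) in four states, three replicas per state.  Exercises
# every analysis stage end-to-end in seconds.
seed: 7
output_dir: demo_out
system:
  n_residues: 16
  atoms_per_residue: 4   # N, CA, C, O so backbone selections resolve
  spacing: 2.4           # i,i+2 residue pairs sit in 5 A contact
  chain_split: 8         # residues 0-7 -> subunit A, 8-15 -> subunit B
n_replicas: 3
n_frames: 240
analysis_window: 0.5     # trailing fraction used by every analysis stage
reference_window: 0.25   # trailing fraction averaged into the reference
states:
  apo:
    noise_sigma: 0.18
    modes:
      - residues: [2, 3, 4, 10, 11]
        direction: [0.0, 1.0, 0.0]
        amplitude: 0.8
  holo:
    noise_sigma: 0.18
    modes:
      - residues: [2, 3, 4, 10, 11]
        direction: [0.0, 1.0, 0.0]
        amplitude: 0.8
    chain:                     # planted communication chain
      residues: [1, 4, 7, 10, 13]
      corr: 0.9
      amplitude: 0.6
    displaced_block: [12, 13, 14, 15]
    displacement: [0.0, 0.0, 6.0]
  holo_atp:
    noise_sigma: 0.1
    modes:
      - residues: [2, 3, 4]
        direction: [0.0, 1.0, 0.0]
        amplitude: 0.3
  basins:                      # discrete two-conformer mixture, 55/45
    mixture:
      weights: [0.55, 0.45]
      block: [13]
      displacements:
        - [-1.2, 0.0, 0.0]
        - [1.2, 0.0, 0.0]
      jitter_sigma: 0.1
stages:
  reference_state: holo_atp
  fit_selection: backbone   # CA atoms of the scaffold are collinear
  analysis_selection: backbone
  contact_cutoff: 5.0
  exclude_bonded: 1
  dpn_threshold: 5.0
  dpn_pair: [apo, holo]
  ed_modes: 4
  wisp:
    state: holo
    source: 1
    sink: 13
    mode: within_delta
    k_or_delta: 0.5
  cluster:
    state: basins
    k: 2
    sieve: 10
  site:
    residues: [2, 3, 4]
    distance_pair:
      state: apo
      group_a: 3
      group_b: 5
      contact_cutoff: 6.0
    orientation:
      state: basins
      switch: 13
      partner_a: 12
      partner_b: 14
      contact_cutoff: 4.0
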