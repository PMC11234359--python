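# Default parameter profile for the trypsin-BPTI(-variant) unbinding analyses.
# Values in the "protocol" sections are the study's simulation/analysis
# defaults; the toy_landscape block holds the calibration constants of the
# reduced Langevin model (chosen so the prebound dwell is observable at the
# default random-force magnitude).

collective_variables:
  enzyme_chain: E
  ligand_chain: I
  T2_residues: [233, 241]   # backbone Val233-Ala241
  T3_residues: [46, 67]     # backbone Gln46-Leu67
  B2_residues: [48, 54]     # backbone Ala48-Thr54
  B3_residues: [14, 16]     # backbone Cys14-Ala16

ramd:
  force_magnitude_kjmol_nm: 3500.0
  evaluation_interval_fs: 100.0
  displacement_threshold_nm: 0.0025
  max_time_ns: 40.0
  dissociation_cutoff_nm: 3.4
  timestep_fs: 2.0
  temperature_K: 300.0
  snapshot_ps: 2.0
  # Brownian mobility of the reduced ligand body (calibration constants)
  mass_amu: 6500.0
  friction_per_ps: 10.0

toy_landscape:
  centers_nm: [2.65, 2.85]
  depths_kjmol: [180.0, 240.0]
  widths_nm: [0.040, 0.050]
  inner_wall_nm: 2.40
  outer_wall_nm: 3.60
  wall_k_kjmol_nm2: 50000.0

state_analysis:
  smoothing_window_ps: 200.0
  prebound_low_nm: 2.75
  prebound_high_nm: 3.00
  bound_center_nm: 2.65
  dissociated_above_nm: 3.20
  min_dwell_ns: 1.0

interactions:
  contact_cutoff_nm: 0.35
  hbond_report_threshold: 0.1
  sasa_probe_radius_nm: 0.14
  sasa_sphere_points: 960

umbrella:
  centers_nm: [0.250, 0.300, 0.350, 0.375, 0.400, 0.425, 0.450, 0.475, 0.500, 0.550, 0.600, 0.650, 0.700]
  force_constant_kjmol_nm2: 6276.0
  temperature_K: 300.0
  bootstrap_segments: 5

# Curated fully-bound interface pairs (donor-acceptor labels in the "s" =
# side-chain convention).  These label the hydrogen-bond-like contacts of the
# fully bound complex; the list is curated from structural inspection, not
# machine-derived, and is shipped as configuration for the interaction stage.
interface_pairs:
  curated: true
  pairs:
    - {label: "R17-N–F41-O",  ligand: {residue: 17, atom: N},   enzyme: {residue: 41, atom: O}}
    - {label: "R17-s–H40-O",  ligand: {residue: 17, atom: s},   enzyme: {residue: 40, atom: O}}
    - {label: "I19-N–Y39-OH", ligand: {residue: 19, atom: N},   enzyme: {residue: 39, atom: OH}}
    - {label: "G12-O–Q194-NE2", ligand: {residue: 12, atom: O}, enzyme: {residue: 194, atom: NE2}}
    - {label: "P13-N–G214-O", ligand: {residue: 13, atom: N},   enzyme: {residue: 214, atom: O}}
    - {label: "C14-O–Q194-s", ligand: {residue: 14, atom: O},   enzyme: {residue: 194, atom: s}}
    - {label: "X15-N–S197-OG", ligand: {residue: 15, atom: N},  enzyme: {residue: 197, atom: OG}}
    - {label: "X15-O–G195-N", ligand: {residue: 15, atom: O},   enzyme: {residue: 195, atom: N}}
    - {label: "A16-N–Q194-OE1", ligand: {residue: 16, atom: N}, enzyme: {residue: 194, atom: OE1}}
    - {label: "R39-s–N97-OD1", ligand: {residue: 39, atom: s},  enzyme: {residue: 97, atom: OD1}}
    - {label: "R39-s–N97-O",  ligand: {residue: 39, atom: s},   enzyme: {residue: 97, atom: O}}
    - {label: "K46-s–S110-O", ligand: {residue: 46, atom: s},   enzyme: {residue: 110, atom: O}}
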