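# Demo pipeline: a synthetic 5 μM open-form-mutant equilibrium experiment,
# a reduction-kinetics series, a bilirubin assay, and the summary table.
# Extinction coefficients are listed in mM^-1 cm^-1; masses in g/mol.
species:
  heme_rHO1: {molar_mass: 30000, vbar: 0.73, extinction: {455: 15.1, 406: 140}}
  dTGEE: {molar_mass: 69600, vbar: 0.73, extinction: {455: 23.8}}

run:
  rpm: 15000
  temp_C: 25
  density: 1.004          # g/mL, 0.1 M potassium phosphate
  path_length_cm: 1.2
  window_cm: [6.90, 7.20] # r0 defaults to the window midpoint

assay_constants:
  eps_bilirubin_468: 43.5 # mM^-1 cm^-1, user-supplied literature value

fit: {seed: 17, n_starts: 8, alpha: 0.05}

pipeline:
  seed: 17
  sedeq:
    - name: dtgee_5uM
      species: [heme_rHO1, dTGEE]
      kd_uM: 0.178
      totals_uM: [5, 5]
      noise_sd: 0.005
  reduction:
    - name: rcpr_like
      rate_constant_per_min: 122
      concentrations_uM: [0.010, 0.020, 0.030]
      heme_conc_uM: 4.3
  assay:
    - name: rcpr_assay
      turnover_per_min: 1.96
      ho1_conc_uM: 0.5
  table:
    control: rCPR
    ho_activity:
      rCPR: [1.96, 0.35]
      147CC514: [0.229, 0.0037]
      IAM/DTT-treated rCPR: [1.17, 0.0024]
      IAM/DTT-treated 147CC514: [1.25, 0.197]
    rate_constant:
      rCPR: [122, 3.8]
      147CC514: [23.9, 5.1]
      DTT-treated rCPR: [130, 10.8]
      DTT-treated 147CC514: [112, 23.6]
      dTGEE: [0.250]
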