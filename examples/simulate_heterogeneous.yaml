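n_mp_events: 10000
seed: 1
species:
- elution_ml: 8.6
  full: true
  genome_mass_da: 1453890.9
  kind: capsid
  label: full
  mass_kda: 5213.8909
  molar_ext_scale: 1.0
  monomer: true
  number_conc_per_ml: 1000000000000.0
  sigma_v_ml: 0.15
- elution_ml: 8.6
  full: false
  genome_mass_da: 0.0
  kind: capsid
  label: empty
  mass_kda: 3760.0
  molar_ext_scale: 1.0
  monomer: true
  number_conc_per_ml: 3000000000000.0
  sigma_v_ml: 0.15
- elution_ml: 8.6
  full: false
  genome_mass_da: 508861.81499999994
  kind: capsid
  label: partial_low
  mass_kda: 4268.861815
  molar_ext_scale: 1.0
  monomer: true
  number_conc_per_ml: 3500000000000.0
  sigma_v_ml: 0.15
- elution_ml: 8.6
  full: false
  genome_mass_da: 1134034.902
  kind: capsid
  label: partial_high
  mass_kda: 4894.034902
  molar_ext_scale: 1.0
  monomer: true
  number_conc_per_ml: 2499999999999.9995
  sigma_v_ml: 0.15
- elution_ml: 7.0
  full: false
  genome_mass_da: 2907781.8
  kind: capsid
  label: aggregate
  mass_kda: 10427.7818
  molar_ext_scale: 1.0
  monomer: false
  number_conc_per_ml: 500000000000.0
  sigma_v_ml: 0.12
- elution_ml: 10.5
  full: false
  genome_mass_da: 800000.0
  kind: dna
  label: free_dna
  mass_kda: 500.0
  molar_ext_scale: 1.0
  monomer: true
  number_conc_per_ml: 5000000000000.0
  sigma_v_ml: 0.2
- elution_ml: 11.2
  full: false
  genome_mass_da: 0.0
  kind: protein
  label: protein_frag
  mass_kda: 60.0
  molar_ext_scale: 0.01
  monomer: true
  number_conc_per_ml: 20000000000000.0
  sigma_v_ml: 0.2
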