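# soubakit run configuration (paths relative to this file)
solenoid_pdb = solenoid.pdb
template_pdb = template_complex.pdb
template_uba_chain = T
template_ub_chain = V
titration_manifest = titration_manifest.tsv
protein_uM = 500.0
itc_thermogram = itc_mono.tsv
itc_cell_uM = 150.0
itc_syringe_uM = 3000.0
itc_injections = 38
itc_injection_uL = 1.0
pre_observed = pre_k6c_observed.tsv
pre_sites = U1:6,U1:39,U1:48,U1:57
csp_threshold_ppm = 0.2
clash_cutoff_A = 2.4
linkage_threshold_A = 9.0
pre_ratio_threshold = 0.7
seed = 20210
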