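# Small packaged study configuration (synthetic): exercises the full
# pipeline in seconds while keeping every stage non-trivial.
n_genes_per_species: 150
probes_per_set: 11
probe_length: 25
frac_de: 0.12
frac_crosshyb_probes: 0.05
contamination_coef: 0.25
noise_sd: 0.25
seed: 11
niche_signatures:
  HSC-niche: [31, 14]
  UGM-niche: [100, 15]
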