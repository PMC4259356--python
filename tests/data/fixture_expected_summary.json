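{
  "curation": {
    "fractions": {
      "core": 0.722222,
      "inflammatory-shared": 0.111111,
      "osteotropic": 0.111111,
      "universal": 0.055556
    },
    "n_core": 13,
    "stage_removed": {
      "inflammatory": 2,
      "non-osteotropic-cancer": 1,
      "osteotropic-primary": 2
    }
  },
  "de": {
    "C4-2B": {
      "n_down": 8,
      "n_selected": 17,
      "n_up": 9,
      "threshold": 1e-05
    },
    "VCaP": {
      "n_down": 8,
      "n_selected": 18,
      "n_up": 10,
      "threshold": 3e-05
    }
  },
  "masking": {
    "n_flagged": 82,
    "n_planted": 82,
    "n_probes": 1650,
    "n_probesets_dropped": 0,
    "sensitivity": 1.0,
    "specificity": 1.0
  },
  "motif": {
    "ef": 1.993,
    "freq_background": 0.308769,
    "freq_cluster": 0.615385,
    "motif": "SYN_MAZ",
    "n_resamples": 5000,
    "p": 0.022396,
    "reported": false,
    "skipped": false
  },
  "n_genes": 150,
  "obbmst": {
    "concordance_r2": 0.99858,
    "n_common": 17,
    "n_discordant": 0,
    "n_total": 18,
    "n_unique_a": 0,
    "n_unique_b": 1
  },
  "overlaps": {
    "HSC-niche:core": {
      "K": 31,
      "N": 150,
      "coverage_pct": 35.5,
      "fold": 4.0943,
      "k": 11,
      "n": 13,
      "p": 3.34e-07
    },
    "HSC-niche:obbmst": {
      "K": 31,
      "N": 150,
      "coverage_pct": 45.2,
      "fold": 3.7634,
      "k": 14,
      "n": 18,
      "p": 2.7e-08
    },
    "UGM-niche:core": {
      "K": 100,
      "N": 150,
      "coverage_pct": 11.0,
      "fold": 1.2692,
      "k": 11,
      "n": 13,
      "p": 0.127370721
    },
    "UGM-niche:obbmst": {
      "K": 100,
      "N": 150,
      "coverage_pct": 15.0,
      "fold": 1.25,
      "k": 15,
      "n": 18,
      "p": 0.087432406
    }
  },
  "seed": 11
}
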