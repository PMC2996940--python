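{
  "agreement_by_bootstrap": {
    "fraction_high": 0.8461538461538461,
    "fraction_low": 1.0,
    "n_high": 13,
    "n_low": 1,
    "n_unknown_bootstrap": 0,
    "threshold": 90.0
  },
  "binning": {
    "i-i_vs_i-cni": {
      "boundaries": [
        0.60875,
        0.6537499999999999,
        0.665,
        0.7150000000000001,
        0.74375,
        0.76,
        0.7946875,
        0.83125,
        0.8674999999999999
      ],
      "counts_type1": [
        0,
        0,
        0,
        0,
        0,
        0,
        1,
        2,
        4,
        10
      ],
      "counts_type2": [
        13,
        3,
        0,
        3,
        0,
        3,
        0,
        0,
        2,
        0
      ],
      "log2_ratio": [
        null,
        null,
        null,
        null,
        null,
        null,
        null,
        null,
        0.5497048631627032,
        null
      ],
      "mean_ipc_type1": [
        null,
        null,
        null,
        null,
        null,
        null,
        0.8,
        0.7857142857142857,
        0.8538752913752914,
        0.804906204906205
      ],
      "mean_ipc_type2": [
        0.3097680097680098,
        0.2074074074074074,
        null,
        0.24074074074074073,
        null,
        0.4222222222222222,
        null,
        null,
        0.5833333333333333,
        null
      ]
    },
    "o-o_vs_o-cno": {
      "boundaries": [
        0.52875,
        0.595,
        0.6178125,
        0.655,
        0.67875,
        0.7128125,
        0.74375,
        0.7887500000000001,
        0.82125
      ],
      "counts_type1": [
        0,
        0,
        1,
        2,
        2,
        1,
        7,
        9,
        4,
        14
      ],
      "counts_type2": [
        21,
        7,
        4,
        6,
        1,
        3,
        6,
        2,
        0,
        4
      ],
      "log2_ratio": [
        null,
        null,
        1.418312631311705,
        0.7345388567716664,
        -0.6780719051126377,
        0.7914133781885828,
        1.4051093562501915,
        0.5053959357822758,
        null,
        0.22542283337822122
      ],
      "mean_ipc_type1": [
        null,
        null,
        0.9333333333333333,
        0.7333333333333334,
        0.35714285714285715,
        0.7692307692307693,
        0.7022215879358737,
        0.774279750750339,
        0.5621794871794872,
        0.6309535702392844
      ],
      "mean_ipc_type2": [
        0.32345220916649486,
        0.40272108843537413,
        0.3492063492063492,
        0.4407407407407407,
        0.5714285714285714,
        0.4444444444444444,
        0.26515151515151514,
        0.5454545454545454,
        null,
        0.5396825396825397
      ]
    }
  },
  "cno_cni_availability": {
    "fraction_both": 0.6666666666666666,
    "fraction_either": 0.0,
    "fraction_neither": 0.3333333333333333,
    "n_members": 57
  },
  "consistency_sets": {
    "focal_species": "spA",
    "n_ambiguous": 0,
    "n_only_consistent": 21,
    "n_only_inconsistent": 3,
    "n_oversize_clusters_removed": 0,
    "oversize_clusters": []
  },
  "go_enrichment": {
    "n_significant": 0,
    "n_terms_tested": 30,
    "representatives": [],
    "significant_terms": []
  },
  "mean_ipc": {
    "i-cni": 0.3250396825396825,
    "i-i": 0.7983500626357769,
    "o-cno": 0.38892080142080143,
    "o-o": 0.6577573162131986
  },
  "mww_p": {
    "i-i_vs_i-cni": 0.00014028448265567415,
    "o-o_vs_o-cno": 0.0004965460054854768
  },
  "n_clusters": 20,
  "n_clusters_mitochondrial_excluded": 0,
  "n_multi_clusters": 14,
  "n_values": {
    "i-cni": 10,
    "i-i": 14,
    "o-cno": 13,
    "o-o": 20
  },
  "pfam_enrichment": {
    "n_significant": 0,
    "n_terms_tested": 10,
    "representatives": [],
    "significant_terms": []
  },
  "property_tests": {
    "length_aa": {
      "p": 1.0,
      "percent_difference": 0.0
    },
    "n_introns": {
      "p": 0.42403893323131625,
      "percent_difference": -19.00826446280991
    },
    "n_pseudo_domains": {
      "p": 0.4407184982223995,
      "percent_difference": -23.636363636363633
    }
  },
  "spearman": {
    "i-cni": {
      "n": 24,
      "p": 0.2947296702098981,
      "rho": 0.2230803930763498
    },
    "i-i": {
      "n": 17,
      "p": 0.394608730494047,
      "rho": -0.22071583761556404
    },
    "o-cno": {
      "n": 54,
      "p": 0.20993761314376666,
      "rho": 0.17337324378971392
    },
    "o-o": {
      "n": 40,
      "p": 0.5478927080740855,
      "rho": -0.09788935227212481
    }
  }
}
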