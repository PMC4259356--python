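{
  "components": {
    "core": [
      "Stro0012",
      "Stro0022",
      "Stro0053",
      "Stro0063",
      "Stro0072",
      "Stro0110",
      "Stro0118",
      "Stro0122",
      "Stro0125",
      "Stro0128",
      "Stro0140",
      "Stro0144",
      "Stro0145"
    ],
    "inflammatory-shared": [
      "Stro0052",
      "Stro0085"
    ],
    "osteotropic": [
      "Stro0035",
      "Stro0055"
    ],
    "universal": [
      "Stro0045"
    ]
  },
  "fractions": {
    "core": 0.722222222,
    "inflammatory-shared": 0.111111111,
    "osteotropic": 0.111111111,
    "universal": 0.055555556
  },
  "stages": [
    {
      "category": "inflammatory",
      "n_removed": 2,
      "remainder": [
        "Stro0012",
        "Stro0022",
        "Stro0035",
        "Stro0045",
        "Stro0053",
        "Stro0055",
        "Stro0063",
        "Stro0072",
        "Stro0110",
        "Stro0118",
        "Stro0122",
        "Stro0125",
        "Stro0128",
        "Stro0140",
        "Stro0144",
        "Stro0145"
      ],
      "removed": [
        "Stro0052",
        "Stro0085"
      ],
      "signatures": [
        "desmoplastic_response",
        "wound_healing",
        "inflammatory_response"
      ]
    },
    {
      "category": "non-osteotropic-cancer",
      "n_removed": 1,
      "remainder": [
        "Stro0012",
        "Stro0022",
        "Stro0035",
        "Stro0053",
        "Stro0055",
        "Stro0063",
        "Stro0072",
        "Stro0110",
        "Stro0118",
        "Stro0122",
        "Stro0125",
        "Stro0128",
        "Stro0140",
        "Stro0144",
        "Stro0145"
      ],
      "removed": [
        "Stro0045"
      ],
      "signatures": [
        "gastric_stroma",
        "pancreatic_stroma",
        "colorectal_stroma"
      ]
    },
    {
      "category": "osteotropic-primary",
      "n_removed": 2,
      "remainder": [
        "Stro0012",
        "Stro0022",
        "Stro0053",
        "Stro0063",
        "Stro0072",
        "Stro0110",
        "Stro0118",
        "Stro0122",
        "Stro0125",
        "Stro0128",
        "Stro0140",
        "Stro0144",
        "Stro0145"
      ],
      "removed": [
        "Stro0035",
        "Stro0055"
      ],
      "signatures": [
        "primary_mammary_stroma",
        "primary_prostate_stroma"
      ]
    }
  ],
  "starting": [
    "Stro0012",
    "Stro0022",
    "Stro0035",
    "Stro0045",
    "Stro0052",
    "Stro0053",
    "Stro0055",
    "Stro0063",
    "Stro0072",
    "Stro0085",
    "Stro0110",
    "Stro0118",
    "Stro0122",
    "Stro0125",
    "Stro0128",
    "Stro0140",
    "Stro0144",
    "Stro0145"
  ]
}
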