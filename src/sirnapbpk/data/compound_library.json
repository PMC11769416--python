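{
  "defaults": {
    "molecular_weight": 16000.0,
    "solute_radius": 1.0,
    "fu": 1.0,
    "Kp": 0.94,
    "ka": 0.84,
    "k_deg_mRNA": 0.06,
    "k_deg_protein": 0.05
  },
  "default_provenance": {
    "molecular_weight": "default-estimate",
    "solute_radius": "literature-fixed",
    "fu": "global-estimate",
    "Kp": "global-estimate",
    "ka": "global-estimate",
    "k_deg_mRNA": "literature-fixed",
    "k_deg_protein": "literature-fixed"
  },
  "compounds": [
    {
      "name": "ALN-AT3",
      "target": "antithrombin",
      "stabilization": "ESC",
      "F": 0.401,
      "k_endosome": 0.012,
      "kon_RISC": 0.00027,
      "Smax": 13.1,
      "SC50": 3.52,
      "gamma": 1.77,
      "regimens": [
        {"route": "SC", "dose": 1.0},
        {"route": "SC", "dose": 2.5},
        {"route": "SC", "dose": 5.0}
      ],
      "provenance": {
        "F": "compound-estimate",
        "k_endosome": "compound-estimate",
        "kon_RISC": "global-estimate",
        "Smax": "compound-estimate",
        "SC50": "compound-estimate",
        "gamma": "compound-estimate"
      }
    },
    {
      "name": "SIAT-2",
      "target": "antithrombin",
      "stabilization": "ESC",
      "F": 0.73,
      "k_endosome": 0.012,
      "kon_RISC": 0.00027,
      "Smax": 13.1,
      "SC50": 3.52,
      "gamma": 1.5,
      "regimens": [
        {"route": "SC", "dose": 2.5},
        {"route": "SC", "dose": 25.0}
      ],
      "provenance": {
        "F": "compound-estimate",
        "k_endosome": "shared-group",
        "kon_RISC": "global-estimate",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "literature-fixed"
      }
    },
    {
      "name": "SITTR-1",
      "target": "transthyretin",
      "stabilization": "ESC",
      "F": 0.632,
      "k_endosome": 0.042,
      "kon_RISC": 0.00027,
      "Smax": 140.2,
      "SC50": 4.07,
      "gamma": 0.42,
      "regimens": [
        {"route": "SC", "dose": 0.5},
        {"route": "SC", "dose": 1.5}
      ],
      "provenance": {
        "F": "shared-group",
        "k_endosome": "shared-group",
        "kon_RISC": "global-estimate",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "shared-group"
      }
    },
    {
      "name": "SITTR-2",
      "target": "transthyretin",
      "stabilization": "ESC",
      "F": 0.632,
      "k_endosome": 0.042,
      "kon_RISC": 0.00027,
      "Smax": 140.2,
      "SC50": 4.07,
      "gamma": 0.42,
      "regimens": [
        {"route": "SC", "dose": 10.0},
        {"route": "IV", "dose": 10.0}
      ],
      "provenance": {
        "F": "shared-group",
        "k_endosome": "shared-group",
        "kon_RISC": "global-estimate",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "shared-group"
      }
    },
    {
      "name": "siF7-1",
      "target": "factor-VII",
      "stabilization": "ESC",
      "F": 0.102,
      "k_endosome": 0.010,
      "kon_RISC": 0.00027,
      "Smax": 85.5,
      "SC50": 1.71,
      "gamma": 1.5,
      "regimens": [
        {"route": "SC", "dose": 2.5}
      ],
      "provenance": {
        "F": "compound-estimate",
        "k_endosome": "compound-estimate",
        "kon_RISC": "global-estimate",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "literature-fixed"
      }
    },
    {
      "name": "siF7-2",
      "target": "factor-VII",
      "stabilization": "ADV-ESC",
      "F": 0.195,
      "k_endosome": 0.0066,
      "kon_RISC": 0.00027,
      "Smax": 85.5,
      "SC50": 1.71,
      "gamma": 1.5,
      "regimens": [
        {"route": "SC", "dose": 0.75}
      ],
      "provenance": {
        "F": "shared-group",
        "k_endosome": "shared-group",
        "kon_RISC": "global-estimate",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "literature-fixed"
      }
    },
    {
      "name": "siF7-3",
      "target": "factor-VII",
      "stabilization": "ADV-ESC",
      "F": 0.195,
      "k_endosome": 0.0066,
      "kon_RISC": 0.00027,
      "Smax": 85.5,
      "SC50": 1.71,
      "gamma": 1.5,
      "regimens": [
        {"route": "SC", "dose": 1.0}
      ],
      "provenance": {
        "F": "shared-group",
        "k_endosome": "shared-group",
        "kon_RISC": "global-estimate",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "literature-fixed"
      }
    },
    {
      "name": "siF9-1",
      "target": "factor-IX",
      "stabilization": "ESC",
      "F": 0.05,
      "k_endosome": 0.0066,
      "kon_RISC": 0.0014,
      "Smax": 40.5,
      "SC50": 1.71,
      "gamma": 1.5,
      "regimens": [
        {"route": "SC", "dose": 2.5}
      ],
      "provenance": {
        "F": "compound-estimate",
        "k_endosome": "compound-estimate",
        "kon_RISC": "shared-group",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "literature-fixed"
      }
    },
    {
      "name": "siF9-2",
      "target": "factor-IX",
      "stabilization": "ADV-ESC",
      "F": 0.103,
      "k_endosome": 0.0042,
      "kon_RISC": 0.0014,
      "Smax": 40.5,
      "SC50": 1.71,
      "gamma": 1.5,
      "regimens": [
        {"route": "SC", "dose": 0.75}
      ],
      "provenance": {
        "F": "compound-estimate",
        "k_endosome": "compound-estimate",
        "kon_RISC": "shared-group",
        "Smax": "shared-group",
        "SC50": "shared-group",
        "gamma": "literature-fixed"
      }
    }
  ]
}
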