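{
  "chelator": "EGTA",
  "comment": [
    "Stepwise association constants for EGTA protonation and metal binding,",
    "log10 scale, quoted at the reference temperature and ionic strength",
    "below (0.1 M, 20 C; critically-selected literature values as used by",
    "the classic chelator calculators).",
    "delta_h_kj values are van't Hoff enthalpies (kJ/mol) applied when",
    "correcting to the working temperature; entries with 0.0 are treated",
    "as temperature-invariant over the 15-40 C range this package targets.",
    "Protonation steps are in order: L+H=HL, HL+H=H2L, H2L+H=H3L, H3L+H=H4L."
  ],
  "reference_temperature_c": 20.0,
  "reference_ionic_strength_m": 0.1,
  "ligand_charge": -4,
  "protonation": [
    {"log_k": 9.47, "delta_h_kj": 0.0},
    {"log_k": 8.85, "delta_h_kj": 0.0},
    {"log_k": 2.66, "delta_h_kj": 0.0},
    {"log_k": 2.00, "delta_h_kj": 0.0}
  ],
  "metals": {
    "ca": {
      "charge": 2,
      "log_k_ml": 10.97,
      "delta_h_ml_kj": -33.9,
      "log_k_mhl": 5.30,
      "delta_h_mhl_kj": 0.0
    },
    "mg": {
      "charge": 2,
      "log_k_ml": 5.21,
      "delta_h_ml_kj": 13.0,
      "log_k_mhl": 3.37,
      "delta_h_mhl_kj": 0.0
    }
  }
}
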