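{
  "schema_version": 1,
  "drugs": {
    "meropenem": {
      "drug_class": "beta_lactam",
      "human_regimen_label": "2 g every 8 h as a 3 h infusion",
      "unbound_fraction_mouse": 0.92,
      "unbound_fraction_human": 0.98,
      "matrices": {
        "plasma": {
          "volume_L_per_kg": 0.04,
          "ka_per_h": 1.34,
          "kel_per_h": 27.13,
          "regimen": {
            "events": [
              {"time_h": 0.0, "amount_mg_per_kg": 65.0},
              {"time_h": 1.25, "amount_mg_per_kg": 65.0},
              {"time_h": 3.5, "amount_mg_per_kg": 45.0},
              {"time_h": 6.0, "amount_mg_per_kg": 45.0}
            ],
            "repeat_interval_h": 8.0,
            "horizon_h": 24.0
          },
          "human_ft_above_pct": {
            "1": 100, "2": 100, "4": 100, "8": 78,
            "16": 50, "32": 19, "64": 0, "128": 0
          }
        },
        "ELF": {
          "volume_L_per_kg": 1.6,
          "ka_per_h": 7.0,
          "kel_per_h": 2.5,
          "regimen": {
            "events": [
              {"time_h": 0.0, "amount_mg_per_kg": 20.0},
              {"time_h": 1.25, "amount_mg_per_kg": 50.0},
              {"time_h": 3.5, "amount_mg_per_kg": 30.0},
              {"time_h": 4.75, "amount_mg_per_kg": 20.0},
              {"time_h": 6.0, "amount_mg_per_kg": 15.0}
            ],
            "repeat_interval_h": 8.0,
            "horizon_h": 24.0
          },
          "human_ft_above_pct": {
            "1": 90, "2": 71, "4": 50, "8": 16,
            "16": 0, "32": 0, "64": 0, "128": 0
          }
        }
      }
    },
    "cefiderocol": {
      "drug_class": "beta_lactam",
      "human_regimen_label": "2 g every 8 h as a 3 h infusion",
      "unbound_fraction_mouse": 0.684,
      "unbound_fraction_human": 0.42,
      "matrices": {
        "plasma": {
          "volume_L_per_kg": 0.19,
          "ka_per_h": 21.71,
          "kel_per_h": 0.74,
          "regimen": {
            "events": [
              {"time_h": 0.0, "amount_mg_per_kg": 5.0},
              {"time_h": 1.0, "amount_mg_per_kg": 7.5},
              {"time_h": 2.0, "amount_mg_per_kg": 10.0},
              {"time_h": 4.0, "amount_mg_per_kg": 3.5},
              {"time_h": 6.0, "amount_mg_per_kg": 1.0}
            ],
            "repeat_interval_h": 8.0,
            "horizon_h": 24.0
          },
          "human_ft_above_pct": {
            "1": 100, "2": 99, "4": 98, "8": 76,
            "16": 48, "32": 11, "64": 0, "128": 0
          }
        },
        "ELF": {
          "volume_L_per_kg": 0.33,
          "ka_per_h": 1.94,
          "kel_per_h": 0.72,
          "regimen": {
            "events": [
              {"time_h": 0.0, "amount_mg_per_kg": 3.75},
              {"time_h": 1.0, "amount_mg_per_kg": 5.0},
              {"time_h": 2.0, "amount_mg_per_kg": 6.25},
              {"time_h": 4.0, "amount_mg_per_kg": 1.75},
              {"time_h": 6.0, "amount_mg_per_kg": 1.0}
            ],
            "repeat_interval_h": 8.0,
            "horizon_h": 24.0
          },
          "human_ft_above_pct": null
        }
      }
    },
    "tobramycin": {
      "drug_class": "aminoglycoside",
      "human_regimen_label": "7 mg/kg as a 30 min infusion",
      "unbound_fraction_mouse": 0.776,
      "unbound_fraction_human": 0.9,
      "matrices": {
        "plasma": {
          "volume_L_per_kg": 0.37,
          "ka_per_h": 23.68,
          "kel_per_h": 0.31,
          "regimen": {
            "events": [
              {"time_h": 0.0, "amount_mg_per_kg": 9.0},
              {"time_h": 3.0, "amount_mg_per_kg": 4.0},
              {"time_h": 6.0, "amount_mg_per_kg": 2.0},
              {"time_h": 9.0, "amount_mg_per_kg": 0.5}
            ],
            "repeat_interval_h": null,
            "horizon_h": 24.0
          },
          "human_ft_above_pct": null
        },
        "ELF": {
          "volume_L_per_kg": 0.79,
          "ka_per_h": 1.74,
          "kel_per_h": 0.35,
          "regimen": {
            "events": [
              {"time_h": 0.0, "amount_mg_per_kg": 4.8},
              {"time_h": 1.5, "amount_mg_per_kg": 3.6},
              {"time_h": 3.0, "amount_mg_per_kg": 2.4},
              {"time_h": 4.5, "amount_mg_per_kg": 2.4},
              {"time_h": 6.5, "amount_mg_per_kg": 2.7},
              {"time_h": 9.0, "amount_mg_per_kg": 2.4},
              {"time_h": 12.5, "amount_mg_per_kg": 1.2},
              {"time_h": 16.0, "amount_mg_per_kg": 1.2}
            ],
            "repeat_interval_h": null,
            "horizon_h": 24.0
          },
          "human_ft_above_pct": null
        }
      },
      "human_reference_indices": {
        "plasma": {"fcmax_mg_L": 18.3, "fauc_mg_h_L": 103.0},
        "ELF": {"fcmax_mg_L": 6.8, "fauc_mg_h_L": 79.0}
      },
      "penetration": {
        "slope_per_h": 0.1223,
        "intercept": 0.1567,
        "r_squared": 0.986,
        "time_range_h": [0.5, 8.0],
        "literature_auc_ratio": 0.69
      },
      "murine_binding_pct_by_dose": {"2.5": 27.1, "5": 20.5, "10": 19.8}
    }
  }
}
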