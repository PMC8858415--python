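{
  "comment": "Retrospective-cohort calibration: per-arm, per-outcome-stratum Me/Q1/Q3 entries for preoperative segment parameters and 24-month outcome scores, plus per-arm demographics and operated-level frequencies. Entries marked assumed=true are package assumptions (see docs/methods.md), not published summaries.",
  "strata": {
    "TDR": {
      "good": {
        "n": 35,
        "outcomes_m24": {
          "odi": {"me": 6, "q1": 6, "q3": 8},
          "vas_back": {"me": 6, "q1": 5, "q3": 8},
          "vas_leg": {"me": 4, "q1": 3, "q3": 5}
        },
        "profile": {
          "linear_translation": {"me": 2, "q1": 1, "q3": 4},
          "sagittal_angulation": {"me": 4, "q1": 3, "q3": 5},
          "general_lordosis": {"me": 30, "q1": 28, "q3": 36},
          "ivd_height": {"me": 10, "q1": 9, "q3": 13},
          "adc": {"me": 1540, "q1": 1280, "q3": 1760},
          "facet_angle": {"me": 50, "q1": 44, "q3": 59}
        },
        "pfirrmann": {"me": 2, "q1": 1, "q3": 2},
        "fujiwara": {"me": 1, "q1": 1, "q3": 2},
        "tropism": "+/-"
      },
      "poor": {
        "n": 7,
        "outcomes_m24": {
          "odi": {"me": 16, "q1": 16, "q3": 18},
          "vas_back": {"me": 14, "q1": 14, "q3": 16},
          "vas_leg": {"me": 16, "q1": 14, "q3": 18}
        },
        "profile": {
          "linear_translation": {"me": 6, "q1": 5, "q3": 7},
          "sagittal_angulation": {"me": 7, "q1": 6, "q3": 8},
          "general_lordosis": {"me": 30, "q1": 26, "q3": 38},
          "ivd_height": {"me": 6, "q1": 5, "q3": 9},
          "adc": {"me": 1050, "q1": 800, "q3": 1150},
          "facet_angle": {"me": 69, "q1": 62, "q3": 74}
        },
        "pfirrmann": {"me": 3, "q1": 3, "q3": 4},
        "fujiwara": {"me": 2, "q1": 1, "q3": 2},
        "tropism": "+/-"
      }
    },
    "MI_TLIF": {
      "good": {
        "n": 64,
        "outcomes_m24": {
          "odi": {"me": 8, "q1": 6, "q3": 8},
          "vas_back": {"me": 9, "q1": 8, "q3": 10},
          "vas_leg": {"me": 6, "q1": 5, "q3": 7}
        },
        "profile": {
          "linear_translation": {"me": 7, "q1": 4, "q3": 11},
          "sagittal_angulation": {"me": 8, "q1": 6, "q3": 9},
          "general_lordosis": {"me": 32, "q1": 28, "q3": 36},
          "ivd_height": {"me": 6, "q1": 5, "q3": 8},
          "adc": {"me": 1180, "q1": 980, "q3": 1230},
          "facet_angle": {"me": 70, "q1": 62, "q3": 78}
        },
        "pfirrmann": {"me": 3, "q1": 3, "q3": 4},
        "fujiwara": {"me": 3, "q1": 2, "q3": 3},
        "tropism": "+"
      },
      "poor": {
        "n": 15,
        "outcomes_m24": {
          "odi": {"me": 26, "q1": 20, "q3": 28},
          "vas_back": {"me": 24, "q1": 22, "q3": 26},
          "vas_leg": {"me": 22, "q1": 21, "q3": 23}
        },
        "profile": {
          "linear_translation": {"me": 3, "q1": 2, "q3": 3},
          "sagittal_angulation": {"me": 3, "q1": 2, "q3": 3},
          "general_lordosis": {"me": 32, "q1": 23, "q3": 38},
          "ivd_height": {"me": 10, "q1": 9, "q3": 12},
          "adc": {"me": 1320, "q1": 1240, "q3": 1520},
          "facet_angle": {"me": 52, "q1": 48, "q3": 56}
        },
        "pfirrmann": {"me": 3, "q1": 3, "q3": 5},
        "fujiwara": {"me": 3, "q1": 3, "q3": 4},
        "tropism": "+/-"
      }
    },
    "O_TLIF": {
      "good": {
        "n": 62,
        "outcomes_m24": {
          "odi": {"me": 8, "q1": 8, "q3": 10},
          "vas_back": {"me": 10, "q1": 10, "q3": 12},
          "vas_leg": {"me": 7, "q1": 7, "q3": 8}
        },
        "profile": {
          "linear_translation": {"me": 7, "q1": 5, "q3": 10},
          "sagittal_angulation": {"me": 8, "q1": 6, "q3": 9},
          "general_lordosis": {"me": 34, "q1": 29, "q3": 41},
          "ivd_height": {"me": 4, "q1": 3, "q3": 7},
          "adc": {"me": 670, "q1": 450, "q3": 930},
          "facet_angle": {"me": 69, "q1": 61, "q3": 82}
        },
        "pfirrmann": {"me": 3, "q1": 3, "q3": 5},
        "fujiwara": {"me": 3, "q1": 3, "q3": 4},
        "tropism": "-"
      },
      "poor": {
        "n": 13,
        "outcomes_m24": {
          "odi": {"me": 32, "q1": 28, "q3": 36},
          "vas_back": {"me": 29, "q1": 27, "q3": 30},
          "vas_leg": {"me": 24, "q1": 22, "q3": 25}
        },
        "profile": {
          "linear_translation": {"me": 3, "q1": 2, "q3": 4},
          "sagittal_angulation": {"me": 3, "q1": 2, "q3": 4},
          "general_lordosis": {"me": 30, "q1": 26, "q3": 39},
          "ivd_height": {"me": 10, "q1": 8, "q3": 14},
          "adc": {"me": 1170, "q1": 1080, "q3": 1660},
          "facet_angle": {"me": 52, "q1": 49, "q3": 56}
        },
        "pfirrmann": {"me": 3, "q1": 2, "q3": 3},
        "fujiwara": {"me": 3, "q1": 2, "q3": 3},
        "tropism": "+"
      }
    }
  },
  "demographics": {
    "TDR": {
      "retrospective": {
        "n": 42,
        "age": {"me": 35, "q1": 32, "q3": 42},
        "bmi": {"me": 25.6, "q1": 23.1, "q3": 29.6},
        "male": 29,
        "female": 13,
        "levels": {"L3-L4": 1, "L4-L5": 17, "L5-S1": 24}
      },
      "prospective": {
        "n": 11,
        "age": {"me": 34, "q1": 30, "q3": 39},
        "bmi": {"me": 24.5, "q1": 23.0, "q3": 28.8},
        "male": 8,
        "female": 3,
        "levels": {"L4-L5": 4, "L5-S1": 7}
      }
    },
    "MI_TLIF": {
      "retrospective": {
        "n": 79,
        "age": {"me": 37, "q1": 33, "q3": 48},
        "bmi": {"me": 26.1, "q1": 23.3, "q3": 29.6},
        "male": 57,
        "female": 22,
        "levels": {"L3-L4": 9, "L4-L5": 28, "L5-S1": 34, "L5-L6": 3, "L6-S1": 5}
      },
      "prospective": {
        "n": 25,
        "age": {"me": 36, "q1": 34, "q3": 41},
        "bmi": {"me": 26.4, "q1": 23.7, "q3": 29.2},
        "male": 16,
        "female": 9,
        "levels": {"L3-L4": 2, "L4-L5": 9, "L5-S1": 14}
      }
    },
    "O_TLIF": {
      "retrospective": {
        "n": 75,
        "age": {"me": 43, "q1": 35, "q3": 54},
        "bmi": {"me": 26.5, "q1": 23.6, "q3": 29.9},
        "male": 51,
        "female": 24,
        "levels": {"L2-L3": 1, "L3-L4": 8, "L4-L5": 27, "L5-S1": 36, "L6-S1": 3}
      },
      "prospective": {
        "n": 23,
        "age": {"me": 45, "q1": 37, "q3": 55},
        "bmi": {"me": 27.0, "q1": 24.1, "q3": 29.2},
        "male": 14,
        "female": 9,
        "levels": {"L3-L4": 2, "L4-L5": 9, "L5-S1": 12}
      }
    }
  },
  "assumptions": {
    "height_loss_fraction": {"me": 0.50, "q1": 0.40, "q3": 0.60, "assumed": true},
    "preop_scores": {
      "odi": {"me": 56, "q1": 48, "q3": 64, "assumed": true},
      "vas_back": {"me": 70, "q1": 62, "q3": 78, "assumed": true},
      "vas_leg": {"me": 62, "q1": 54, "q3": 70, "assumed": true}
    }
  }
}
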