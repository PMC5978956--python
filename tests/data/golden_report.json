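{
  "series": {
    "sequence_name": "SYN_ACR_T1WI",
    "coil_name": "synthetic",
    "fov_mm": 250.0,
    "matrix": [
      256,
      256
    ],
    "phase_encode_axis": "row",
    "n_slices": 11,
    "piu_slice": "S7",
    "slice_roles": {
      "S1": 0,
      "S2": 1,
      "S3": 2,
      "S4": 3,
      "S5": 4,
      "S6": 5,
      "S7": 6,
      "S8": 7,
      "S9": 8,
      "S10": 9,
      "S11": 10
    }
  },
  "protocol": "acr_standard",
  "criteria_id": "custom",
  "tool_version": "0.1.0",
  "timestamp": null,
  "overall_pass": true,
  "metrics": [
    {
      "name": "gd_s1_0",
      "value": -0.22749700159417777,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": 0.0,
        "slice": "S1",
        "measured_mm": 190.43224430302894,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s1_90",
      "value": 0.1388764627129029,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": 90.0,
        "slice": "S1",
        "measured_mm": 189.73613472084548,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s1_p45",
      "value": -0.05866691354647831,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": 45.0,
        "slice": "S1",
        "measured_mm": 190.1114671357383,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s1_m45",
      "value": -0.06196414265490914,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": -45.0,
        "slice": "S1",
        "measured_mm": 190.11773187104433,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s5_0",
      "value": 0.13752730112604408,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": 0.0,
        "slice": "S5",
        "measured_mm": 189.73869812786052,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s5_90",
      "value": 0.1367457574714368,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": 90.0,
        "slice": "S5",
        "measured_mm": 189.74018306080427,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s5_p45",
      "value": -0.04927349779345484,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": 45.0,
        "slice": "S5",
        "measured_mm": 190.09361964580756,
        "actual_mm": 190.0
      }
    },
    {
      "name": "gd_s5_m45",
      "value": -0.05334672925216996,
      "units": "%",
      "criterion": "|value| <= 1.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "angle_deg": -45.0,
        "slice": "S5",
        "measured_mm": 190.10135878557912,
        "actual_mm": 190.0
      }
    },
    {
      "name": "sp_s1",
      "value": -0.00048134400365285046,
      "units": "mm",
      "criterion": "|value| <= 5.0 mm",
      "passed": "pass",
      "display": "-0.00 mm (inferior)",
      "provenance": {
        "left_bar_mm": 40.03519337828135,
        "right_bar_mm": 40.036156066288655,
        "delta_sp_mm": -0.0009626880073057009
      }
    },
    {
      "name": "sp_s11",
      "value": 0.0015209060569532085,
      "units": "mm",
      "criterion": "|value| <= 5.0 mm",
      "passed": "pass",
      "display": "+0.00 mm (superior)",
      "provenance": {
        "left_bar_mm": 40.035148243811044,
        "right_bar_mm": 40.03210643169714,
        "delta_sp_mm": 0.003041812113906417
      }
    },
    {
      "name": "st",
      "value": 4.979108146553378,
      "units": "mm",
      "criterion": "|value - 5.0| <= 0.7 mm",
      "passed": "pass",
      "display": "",
      "provenance": {
        "top_mm": 49.79836018088362,
        "bottom_mm": 49.78380487764173
      }
    },
    {
      "name": "piu",
      "value": 96.49989151242524,
      "units": "%",
      "criterion": ">= 82.0 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "slice": "S7",
        "s_max": 1017.280679785331,
        "s_min": 948.4770274299344,
        "max_center_px": [
          99,
          181
        ],
        "min_center_px": [
          169,
          64
        ]
      }
    },
    {
      "name": "gr",
      "value": 0.11026969084434117,
      "units": "%",
      "criterion": "<= 2.5 %",
      "passed": "pass",
      "display": "",
      "provenance": {
        "slice": "S7",
        "signed_pct": -0.11026969084434117,
        "roi_means": {
          "top": 2.0256410256410255,
          "bottom": 2.004843304843305,
          "left": 3.044064577397911,
          "right": 3.168755935422602
        },
        "phantom_mean": 989.544890180571,
        "rois": {
          "top": [
            9,
            22,
            87,
            168
          ],
          "bottom": [
            234,
            247,
            87,
            168
          ],
          "left": [
            87,
            168,
            9,
            22
          ],
          "right": [
            87,
            168,
            234,
            247
          ]
        }
      }
    },
    {
      "name": "hcsr_lr",
      "value": 0.9,
      "units": "mm",
      "criterion": "<= 1.0 mm",
      "passed": "pass",
      "display": "0.9",
      "provenance": {
        "per_block": {
          "1.1mm/horiz": true,
          "1.0mm/horiz": true,
          "0.9mm/horiz": true,
          "1.1mm/vert": true,
          "1.0mm/vert": true,
          "0.9mm/vert": true
        },
        "overridden": {}
      }
    },
    {
      "name": "hcsr_ap",
      "value": 0.9,
      "units": "mm",
      "criterion": "<= 1.0 mm",
      "passed": "pass",
      "display": "0.9",
      "provenance": {
        "per_block": {
          "1.1mm/horiz": true,
          "1.0mm/horiz": true,
          "0.9mm/horiz": true,
          "1.1mm/vert": true,
          "1.0mm/vert": true,
          "0.9mm/vert": true
        },
        "overridden": {}
      }
    },
    {
      "name": "lcd",
      "value": 40.0,
      "units": "spokes",
      "criterion": ">= 37 spokes",
      "passed": "pass",
      "display": "",
      "provenance": {
        "per_slice": {
          "S8": 10,
          "S9": 10,
          "S10": 10,
          "S11": 10
        },
        "contrast_pct": {
          "S8": 1.4,
          "S9": 2.5,
          "S10": 3.6,
          "S11": 5.1
        },
        "overridden": {}
      }
    }
  ]
}
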