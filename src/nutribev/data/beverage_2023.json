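{
  "name": "beverage_2023",
  "version": "v2023",
  "water_only_A": true,
  "letter_bands": [["B", 2], ["C", 6], ["D", 9], ["E", null]],
  "components": {
    "energy": {
      "polarity": "unfavorable",
      "unit": "kJ/100mL",
      "bands": [[30, 0], [90, 1], [150, 2], [210, 3], [240, 4], [270, 5], [300, 6], [330, 7], [360, 8], [390, 9]],
      "top_points": 10
    },
    "sugars": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[0.5, 0], [2.0, 1], [3.5, 2], [5.0, 3], [6.0, 4], [7.0, 5], [8.0, 6], [9.0, 7], [10.0, 8], [11.0, 9]],
      "top_points": 10
    },
    "satfat": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[1, 0], [2, 1], [3, 2], [4, 3], [5, 4], [6, 5], [7, 6], [8, 7], [9, 8], [10, 9]],
      "top_points": 10
    },
    "salt": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[0.2, 0], [0.4, 1], [0.6, 2], [0.8, 3], [1.0, 4], [1.2, 5], [1.4, 6], [1.6, 7], [1.8, 8], [2.0, 9], [2.2, 10], [2.4, 11], [2.6, 12], [2.8, 13], [3.0, 14], [3.2, 15], [3.4, 16], [3.6, 17], [3.8, 18], [4.0, 19]],
      "top_points": 20
    },
    "nns": {
      "polarity": "unfavorable",
      "unit": "present",
      "bands": [[0, 0]],
      "top_points": 4
    },
    "protein": {
      "polarity": "favorable",
      "unit": "g/100mL",
      "bands": [[1.2, 0], [1.5, 1], [1.8, 2], [2.1, 3], [2.4, 4], [2.7, 5], [3.0, 6]],
      "top_points": 7
    },
    "fiber": {
      "polarity": "favorable",
      "unit": "g/100mL",
      "bands": [[3.0, 0], [4.1, 1], [5.2, 2], [6.3, 3], [7.4, 4]],
      "top_points": 5
    },
    "fvl": {
      "polarity": "favorable",
      "unit": "%",
      "bands": [[40, 0], [60, 2], [80, 4]],
      "top_points": 6
    }
  }
}
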