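{
  "name": "food_2015",
  "version": "v2015",
  "water_only_A": false,
  "letter_bands": [["A", -1], ["B", 2], ["C", 10], ["D", 18], ["E", null]],
  "components": {
    "energy": {
      "polarity": "unfavorable",
      "unit": "kJ/100mL",
      "bands": [[335, 0], [670, 1], [1005, 2], [1340, 3], [1675, 4], [2010, 5], [2345, 6], [2680, 7], [3015, 8], [3350, 9]],
      "top_points": 10
    },
    "sugars": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[4.5, 0], [9.0, 1], [13.5, 2], [18.0, 3], [22.5, 4], [27.0, 5], [31.0, 6], [36.0, 7], [40.0, 8], [45.0, 9]],
      "top_points": 10
    },
    "satfat": {
      "polarity": "unfavorable",
      "unit": "g/100mL",
      "bands": [[1, 0], [2, 1], [3, 2], [4, 3], [5, 4], [6, 5], [7, 6], [8, 7], [9, 8], [10, 9]],
      "top_points": 10
    },
    "sodium": {
      "polarity": "unfavorable",
      "unit": "mg/100mL",
      "bands": [[90, 0], [180, 1], [270, 2], [360, 3], [450, 4], [540, 5], [630, 6], [720, 7], [810, 8], [900, 9]],
      "top_points": 10
    },
    "protein": {
      "polarity": "favorable",
      "unit": "g/100mL",
      "bands": [[1.6, 0], [3.2, 1], [4.8, 2], [6.4, 3], [8.0, 4]],
      "top_points": 5
    },
    "fiber": {
      "polarity": "favorable",
      "unit": "g/100mL",
      "bands": [[0.7, 0], [1.4, 1], [2.1, 2], [2.8, 3], [3.5, 4]],
      "top_points": 5
    },
    "fvl": {
      "polarity": "favorable",
      "unit": "%",
      "bands": [[40, 0], [60, 1], [80, 2]],
      "top_points": 5
    }
  }
}
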