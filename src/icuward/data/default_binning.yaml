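# Default binning tables for feature extraction.
#
# vitals: per vital type, per age bin, three strictly increasing boundaries
# splitting the value axis into four ordered risk categories.  With
# ascending order (default) values below the first boundary map to C1 and
# values at/above the last map to C4; with `descending: true` the labels are
# reversed so that low values are the high-risk categories (pulse oximetry).
#
# labs: per analyte, the (low, high) normal-range bounds mapping a value to
# Low / Normal / High.
#
# These boundaries are configuration, not claims about any institution's
# reference ranges; edit freely.
vitals:
  heart_rate:
    "<1":   [140, 160, 180]
    "1-4":  [130, 150, 170]
    "5-11": [120, 140, 160]
    "12-17": [100, 120, 140]
    ">=18": [90, 110, 130]
  respiratory_rate:
    "<1":   [40, 50, 60]
    "1-4":  [32, 40, 50]
    "5-11": [26, 34, 44]
    "12-17": [22, 30, 40]
    ">=18": [20, 28, 36]
  temperature:
    "<1":   [37.8, 38.5, 39.5]
    "1-4":  [37.8, 38.5, 39.5]
    "5-11": [37.8, 38.5, 39.5]
    "12-17": [37.8, 38.5, 39.5]
    ">=18": [37.8, 38.5, 39.5]
  systolic_bp:
    descending: true
    "<1":   [65, 75, 85]
    "1-4":  [70, 80, 90]
    "5-11": [75, 85, 95]
    "12-17": [80, 90, 100]
    ">=18": [85, 95, 105]
  oxygen_saturation:
    descending: true
    "<1":   [88, 92, 95]
    "1-4":  [88, 92, 95]
    "5-11": [88, 92, 95]
    "12-17": [88, 92, 95]
    ">=18": [88, 92, 95]
labs:
  sodium: [135, 145]
  potassium: [3.5, 5.0]
  glucose: [70, 140]
  creatinine: [0.3, 1.0]
  bicarbonate: [20, 28]
  wbc: [5.0, 14.5]
  hematocrit: [34, 44]
  hemoglobin: [11, 15]
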