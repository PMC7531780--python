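# Clinical discretisation cutoffs, version 1.
#
# Bin convention: lo/hi omitted means unbounded on that side; lo_incl defaults
# to true and hi_incl to false, i.e. "[lo, hi)". Deviations (e.g. the HDL
# middle bin closed on both ends) are spelled out explicitly. `range` is the
# plausible span of raw measurements used by the synthetic cohort generator
# when it samples a raw value inside a chosen bin; it never affects
# discretisation itself.
version: 1
attributes:
  Sex:
    kind: categorical
    codes: [1, 2]          # 1 = female, 2 = male
  Age:
    kind: interval
    unit: yr
    range: [35, 60]
    bins:
      - {code: 1, hi: 50, hi_incl: true}
      - {code: 2, lo: 50, lo_incl: false}
  BMI:
    kind: interval
    unit: kg/m^2
    range: [15, 45]
    bins:
      - {code: 1, hi: 18.5}                 # underweight
      - {code: 2, lo: 18.5, hi: 25}         # normal weight
      - {code: 3, lo: 25, hi: 30}           # overweight
      - {code: 4, lo: 30, hi: 35}           # obesity class I
      - {code: 5, lo: 35}                   # obesity class II-III
  WHR:
    kind: stratified_sex_age
    unit: cm/cm
    range: [0.55, 1.30]
    strata:
      female:
        - age_hi: 39
          bins:
            - {code: 1, hi: 0.72}
            - {code: 2, lo: 0.72, hi: 0.79}
            - {code: 3, lo: 0.79, hi: 0.84, hi_incl: true}
            - {code: 4, lo: 0.84, lo_incl: false}
        - age_hi: 49
          bins:
            - {code: 1, hi: 0.73}
            - {code: 2, lo: 0.73, hi: 0.80}
            - {code: 3, lo: 0.80, hi: 0.87, hi_incl: true}
            - {code: 4, lo: 0.87, lo_incl: false}
        - age_hi: null
          bins:
            - {code: 1, hi: 0.74}
            - {code: 2, lo: 0.74, hi: 0.82}
            - {code: 3, lo: 0.82, hi: 0.88, hi_incl: true}
            - {code: 4, lo: 0.88, lo_incl: false}
      male:
        - age_hi: 39
          bins:
            - {code: 1, hi: 0.84}
            - {code: 2, lo: 0.84, hi: 0.92}
            - {code: 3, lo: 0.92, hi: 0.96, hi_incl: true}
            - {code: 4, lo: 0.96, lo_incl: false}
        - age_hi: 49
          bins:
            - {code: 1, hi: 0.88}
            - {code: 2, lo: 0.88, hi: 0.96}
            - {code: 3, lo: 0.96, hi: 1.00, hi_incl: true}
            - {code: 4, lo: 1.00, lo_incl: false}
        - age_hi: null
          bins:
            - {code: 1, hi: 0.90}
            - {code: 2, lo: 0.90, hi: 0.97}
            - {code: 3, lo: 0.97, hi: 1.02, hi_incl: true}
            - {code: 4, lo: 1.02, lo_incl: false}
  AC:
    kind: stratified_sex
    unit: cm
    range: [60, 130]
    strata:
      female:
        - {code: 1, hi: 80}                 # low risk
        - {code: 2, lo: 80, hi: 88}         # high risk
        - {code: 3, lo: 88}                 # very high risk
      male:
        - {code: 1, hi: 94}
        - {code: 2, lo: 94, hi: 102}
        - {code: 3, lo: 102}
  FPG:
    kind: interval
    unit: mg/dL
    range: [70, 320]
    bins:
      - {code: 1, hi: 100}                  # normoglycemic
      - {code: 2, lo: 100, hi: 126}         # prediabetes / high risk
      - {code: 3, lo: 126}                  # established diabetes
  INS:
    kind: interval
    unit: U/L
    range: [2, 60]
    bins:
      - {code: 1, hi: 25, hi_incl: true}    # normal
      - {code: 2, lo: 25, lo_incl: false}   # altered
  HbA1c:
    kind: interval
    unit: "%"
    range: [4, 14]
    bins:
      - {code: 1, hi: 5.7}                  # normoglycemic
      - {code: 2, lo: 5.7, hi: 6.5}         # prediabetes / high risk
      - {code: 3, lo: 6.5, hi: 8}           # transitory decompensation
      - {code: 4, lo: 8}                    # defined decompensation
  HOMA-IR:
    kind: interval
    range: [0.3, 12]
    bins:
      - {code: 1, hi: 2.15, hi_incl: true}
      - {code: 2, lo: 2.15, lo_incl: false}
  TC:
    kind: interval
    unit: mg/dL
    range: [100, 320]
    bins:
      - {code: 1, hi: 150}                  # optimal
      - {code: 2, lo: 150, hi: 200}
      - {code: 3, lo: 200, hi: 240}
      - {code: 4, lo: 240}
  HDL:
    kind: interval
    unit: mg/dL
    range: [20, 90]
    bins:
      - {code: 1, hi: 40}                        # low
      - {code: 2, lo: 40, hi: 60, hi_incl: true} # closed on both ends, as published
      - {code: 3, lo: 60, lo_incl: false}
  LDL:
    kind: interval
    unit: mg/dL
    range: [50, 260]
    bins:
      - {code: 1, hi: 100}                  # optimal
      - {code: 2, lo: 100, hi: 130}
      - {code: 3, lo: 130, hi: 160}
      - {code: 4, lo: 160, hi: 190}
      - {code: 5, lo: 190}
  TG:
    kind: interval
    unit: mg/dL
    range: [50, 300]
    bins:
      - {code: 1, hi: 150}                  # optimal
      - {code: 2, lo: 150, hi: 200}
      - {code: 3, lo: 200}
  N-HDL-C:
    kind: interval
    unit: mg/dL
    range: [60, 300]
    bins:
      - {code: 1, hi: 130}                  # optimal
      - {code: 2, lo: 130, hi: 160}
      - {code: 3, lo: 160, hi: 190}
      - {code: 4, lo: 190, hi: 220}
      - {code: 5, lo: 220}
  VP:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: &pct_low_med_high
      - {code: 1, hi: 30}                        # low
      - {code: 2, lo: 30, hi: 50, hi_incl: true} # medium
      - {code: 3, lo: 50, lo_incl: false}        # high
  GI:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  BOP:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  TNT:
    kind: interval
    range: [15, 32]
    bins:
      - {code: 1, hi: 20, hi_incl: true}    # low number of teeth
      - {code: 2, lo: 20, lo_incl: false}   # high number of teeth
  PPDi3mm:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  PPDi4-5mm:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  PPDi6mm:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins:
      - {code: 1, hi: 30}                   # low
      - {code: 2, lo: 30}                   # medium and high
  CALi2mm:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  CALi3-4mm:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  CALi5mm:
    kind: interval
    unit: "%ts"
    range: [0, 100]
    bins: *pct_low_med_high
  SUPP:
    kind: interval
    unit: "%ts"
    range: [0, 60]
    bins:
      - {code: 1, hi: 1}                    # absence
      - {code: 2, lo: 1, hi: 16}            # moderate
      - {code: 3, lo: 16}                   # severe
  NDI:
    kind: interval
    range: [1.0, 2.6]
    bins:
      - {code: 1, hi: 1.87}
      - {code: 2, lo: 1.87, hi: 2.08}
      - {code: 3, lo: 2.08}
  MNCF:
    kind: interval
    unit: "%"
    range: [0, 14]
    bins:
      - {code: 1, hi: 3.05}
      - {code: 2, lo: 3.05, hi: 7.2}
      - {code: 3, lo: 7.2}
  MNF:
    kind: interval
    unit: "%"
    range: [0, 12]
    bins:
      - {code: 1, hi: 3.5}
      - {code: 2, lo: 3.5, hi: 6.1}
      - {code: 3, lo: 6.1}
  FNB:
    kind: interval
    unit: "%"
    range: [0, 6]
    bins:
      - {code: 1, hi: 1.21}
      - {code: 2, lo: 1.21, hi: 2.7}
      - {code: 3, lo: 2.7}
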