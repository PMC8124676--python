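# Published reference concentrations (mg/kg) and survey table values for the
# five potentially toxic elements in urban green-space soils. Backgrounds are
# regional (Shanghai) and national (China) soil reference values; literature
# rows are mean concentrations reported for other cities.

backgrounds:
  shanghai_background:
    Pb: 25.47
    Cu: 28.59
    Zn: 83.68
    Cr: 75.00
    Cd: 0.13
  china_background:
    Pb: 23.50
    Cu: 20.70
    Zn: 68.00
    Cr: 57.30
    Cd: 0.08

literature:
  seville_spain:    {Pb: 161.0, Cu: 72.00, Zn: 210.0, Cr: 75.00, Cd: null}
  mexico_city:      {Pb: 82.00, Cu: 54.00, Zn: 219.0, Cr: null,  Cd: 116.0}
  konya_turkey:     {Pb: 289.4, Cu: 427.4, Zn: 289.8, Cr: 14.0,  Cd: 21.0}
  stockholm_sweden: {Pb: 104.0, Cu: 47.0,  Zn: 157.0, Cr: 27.0,  Cd: 0.43}
  tunas_cuba:       {Pb: 42.0,  Cu: 94.0,  Zn: 199.0, Cr: 97.0,  Cd: null}
  pensacola_usa:    {Pb: 23.98, Cu: 6.26,  Zn: 33.22, Cr: 9.01,  Cd: 0.13}
  urumqi_china:     {Pb: 43.22, Cu: 42.54, Zn: 94.79, Cr: 30.97, Cd: 0.71}
  guangzhou_china:  {Pb: 240.0, Cu: 176.0, Zn: 586.0, Cr: 78.8,  Cd: 2.41}
  hangzhou_china:   {Pb: 202.1, Cu: 116.0, Zn: 321.4, Cr: 51.25, Cd: 1.59}
  shanghai_2008:    {Pb: 70.69, Cu: 59.25, Zn: 301.4, Cr: 107.9, Cd: 0.52}

# Printed descriptive statistics of the reference 460-sample Shanghai
# green-space survey (mg/kg): inputs for reproducing CV% and enrichment folds.
printed_summary:
  Pb: {mean: 36.96, median: 31.70, min: 13.41, max: 175.8, sd: 20.20, cv: 54.66}
  Cu: {mean: 34.41, median: 30.27, min: 10.09, max: 225.4, sd: 19.04, cv: 55.32}
  Zn: {mean: 130.3, median: 113.6, min: 49.15, max: 1098,  sd: 84.83, cv: 65.10}
  Cr: {mean: 73.09, median: 73.20, min: 38.24, max: 143.2, sd: 10.76, cv: 14.73}
  Cd: {mean: 0.21,  median: 0.17,  min: 0.06,  max: 3.68,  sd: 0.21,  cv: 100.50}

# Fitted log-scale variogram parameters of the reference survey.
printed_variograms:
  Pb: {family: spherical,   nugget: 0.047, partial_sill: 0.133, range_m: 2263.30}
  Cu: {family: gaussian,    nugget: 0.053, partial_sill: 0.128, range_m: 2597.00}
  Zn: {family: gaussian,    nugget: 0.000, partial_sill: 0.141, range_m: 213.98}
  Cr: {family: spherical,   nugget: 0.000, partial_sill: 0.015, range_m: 120.48}
  Cd: {family: exponential, nugget: 0.000, partial_sill: 0.238, range_m: 140.93}

# Reference-survey mean kriging variance by number of points perturbed
# (initial MKV printed both as 131.7 and 131.74 in the source).
printed_mkv:
  initial: 131.7
  initial_alt: 131.74
  perturbed: {50: 128.9, 100: 118.2, 150: 109.1, 200: 102.3}
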