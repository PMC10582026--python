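# Group-level presets for the synthetic metabolic-cart generator.
#
# Each cell is a (mean, sd) pair describing the study population of male
# adolescents with severe obesity: group baseline (W0) and end-of-program
# (W3) anthropometrics, graded-test capacities, fat-oxidation curve
# landmarks, and the substrate totals of one energy-equated training session
# used to calibrate the submaximal-session simulator.
#
# session_fat_gain is a dimensionless multiplier on the fat-oxidation truth
# curve applied only during prolonged submaximal sessions; it emulates the
# upward drift of fat oxidation with exercise duration (which a 5-min-stage
# graded protocol does not express) and is calibrated once against the
# session substrate totals above it.
schema_version: 1
presets:
  COMB_W0:
    group: COMB
    timepoint: W0
    age: {mean: 15.7, sd: 1.7}               # years
    stature: {mean: 1.75, sd: 0.07}          # m
    body_mass: {mean: 117.7, sd: 19.8}       # kg
    ffm: {mean: 65.4, sd: 7.9}               # kg
    bmr: {mean: 7.44, sd: 1.05}              # MJ day-1
    vo2peak: {mean: 2.52, sd: 0.46}          # L min-1
    hrpeak: {mean: 176.0, sd: 4.7}           # bpm
    mfo: {mean: 0.32, sd: 0.07}              # g min-1, fat-curve peak height
    fatmax: {mean: 50.0, sd: 9.0}            # %VO2peak, fat-curve peak location
    crossover: {mean: 74.0, sd: 6.0}         # %VO2peak, fat contribution negligible above
    session_fat_gain: 1.35
    session_targets:
      total_ee_kj: {mean: 1362, sd: 166}
      ee_cho_kj: {mean: 644, sd: 189}
      ee_fat_kj: {mean: 552, sd: 137}
      ee_protein_kj: {mean: 174, sd: 20}
      cho_g: {mean: 39, sd: 11}
      fat_g: {mean: 15, sd: 4}
      protein_g: {mean: 10, sd: 1}
  COMB_W3:
    group: COMB
    timepoint: W3
    age: {mean: 15.8, sd: 1.7}
    stature: {mean: 1.75, sd: 0.07}
    body_mass: {mean: 112.6, sd: 19.2}
    ffm: {mean: 64.7, sd: 7.5}
    bmr: {mean: 7.20, sd: 1.02}
    vo2peak: {mean: 2.81, sd: 0.45}
    hrpeak: {mean: 176.0, sd: 9.1}
    mfo: {mean: 0.36, sd: 0.07}
    fatmax: {mean: 50.0, sd: 9.0}
    crossover: {mean: 74.0, sd: 6.0}
    session_fat_gain: 1.00
    session_targets:
      total_ee_kj: {mean: 1312, sd: 184}
      ee_cho_kj: {mean: 737, sd: 211}
      ee_fat_kj: {mean: 433, sd: 157}
      ee_protein_kj: {mean: 165, sd: 22}
      cho_g: {mean: 44, sd: 13}
      fat_g: {mean: 11, sd: 5}
      protein_g: {mean: 10, sd: 1}
  MICT_W0:
    group: MICT
    timepoint: W0
    age: {mean: 16.2, sd: 1.1}
    stature: {mean: 1.72, sd: 0.07}
    body_mass: {mean: 111.5, sd: 14.8}
    ffm: {mean: 69.2, sd: 7.5}
    bmr: {mean: 8.66, sd: 0.78}
    vo2peak: {mean: 3.60, sd: 0.42}
    hrpeak: {mean: 176.1, sd: 6.8}
    mfo: {mean: 0.41, sd: 0.09}
    fatmax: {mean: 46.0, sd: 8.0}
    crossover: {mean: 74.0, sd: 6.0}
    session_fat_gain: 1.21
    session_targets:
      total_ee_kj: {mean: 1521, sd: 256}
      ee_cho_kj: {mean: 518, sd: 107}
      ee_fat_kj: {mean: 831, sd: 178}
      ee_protein_kj: {mean: 172, sd: 30}
      cho_g: {mean: 31, sd: 6}
      fat_g: {mean: 22, sd: 5}
      protein_g: {mean: 10, sd: 2}
  MICT_W3:
    group: MICT
    timepoint: W3
    age: {mean: 16.3, sd: 1.1}
    stature: {mean: 1.72, sd: 0.07}
    body_mass: {mean: 103.2, sd: 13.9}
    ffm: {mean: 65.0, sd: 8.4}
    bmr: {mean: 8.13, sd: 1.02}
    vo2peak: {mean: 3.62, sd: 0.36}
    hrpeak: {mean: 177.8, sd: 5.6}
    mfo: {mean: 0.41, sd: 0.09}
    fatmax: {mean: 46.0, sd: 8.0}
    crossover: {mean: 74.0, sd: 6.0}
    session_fat_gain: 1.27
    session_targets:
      total_ee_kj: {mean: 1549, sd: 201}
      ee_cho_kj: {mean: 563, sd: 142}
      ee_fat_kj: {mean: 812, sd: 221}
      ee_protein_kj: {mean: 173, sd: 22}
      cho_g: {mean: 34, sd: 9}
      fat_g: {mean: 22, sd: 6}
      protein_g: {mean: 10, sd: 1}
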