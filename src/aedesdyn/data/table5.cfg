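# Baseline simulation parameters (fitted dispersal values plus literature
# rates) and the annular mark-release-recapture layout used to fit them.
parameters:
  D: 18969.0        # m^2/day, fitted to ring counts
  gamma: 0.0625     # 1/day, 8-day maturation, 50% female
  mu1_base: 0.1177  # 1/day, fitted to ring counts
  mu1_insecticide: 0.0
  mu2: 0.0250       # 1/day, larval mortality
  r: 34.0           # eggs/day per female, lifetime average
  e: 0.2400         # 1/day, hatching under ideal humidity
  k: 0.0590         # 1/m^2, aquatic carrying capacity
alpha: 0.0642       # trap detection probability per ring
release:
  M0: 3000
  t: 7.0
annuli:
  edges: [0, 100, 200, 400, 600, 800]
  counts: [0, 2, 12, 20, 17]   # observed Rb-tagged egg detections
  weights: [1, 1, 5, 10, 10]
grid:
  nx: 400
  ny: 400
  dx: 10.0
  origin: [0.0, 0.0]
run:
  dt: 1/48
  t_end: 7.0
  snapshot_times: [7.0]
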