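# Base-case model configuration: single-dose rimegepant 75 mg vs placebo for
# on-demand acute treatment of migraine in China, 2-hour horizon.
#
# Transition probabilities are given as responder counts (successes = responders,
# failures = non-responders within the relevant denominator: the arm total for the
# 2-hour endpoints, the 2-hour responders for the time-to-relief bins).  The
# 120-minute bin and the treatment-ineffectiveness probability are complements and
# are derived on load.  Utilities are per health state; freedom-from-MBS utilities
# are derived as 0.87 x the pain-freedom utility of the same time bin.
name: rimegepant-china-2h
horizon_hours: 2
wtp_per_qald: 734.45
mbs_utility_factor: 0.87
time_bins_min: [15, 30, 45, 60, 90, 120]

arms:
  treatment:
    name: rimegepant
    dose_cost: {base: 219.00, low: 175.20, high: 262.80, sd: 22.24}
    pain_freedom_2h: {successes: 132, failures: 534}
    fmbs_2h: {successes: 336, failures: 330}
    pain_freedom_bins:
      15: {successes: 5, failures: 127}
      30: {successes: 2, failures: 130}
      45: {successes: 15, failures: 117}
      60: {successes: 23, failures: 109}
      90: {successes: 37, failures: 95}
    fmbs_bins:
      15: {successes: 68, failures: 268}
      30: {successes: 44, failures: 292}
      45: {successes: 49, failures: 287}
      60: {successes: 46, failures: 290}
      90: {successes: 69, failures: 267}
  comparator:
    name: placebo
    dose_cost: {base: 0.0, low: 0.0, high: 0.0, sd: 0.0}
    pain_freedom_2h: {successes: 72, failures: 602}
    fmbs_2h: {successes: 241, failures: 433}
    pain_freedom_bins:
      15: {successes: 7, failures: 65}
      30: {successes: 3, failures: 69}
      45: {successes: 5, failures: 67}
      60: {successes: 15, failures: 57}
      90: {successes: 18, failures: 54}
    fmbs_bins:
      15: {successes: 75, failures: 166}
      30: {successes: 25, failures: 216}
      45: {successes: 34, failures: 207}
      60: {successes: 33, failures: 208}
      90: {successes: 47, failures: 194}

utilities:
  pain_freedom:
    15: {base: 0.7573, low: 0.7194, high: 0.7952, sd: 0.1662}
    30: {base: 0.6449, low: 0.6127, high: 0.6771, sd: 0.2817}
    45: {base: 0.6764, low: 0.6426, high: 0.7102, sd: 0.2458}
    60: {base: 0.6420, low: 0.6010, high: 0.6741, sd: 0.2543}
    90: {base: 0.5916, low: 0.5620, high: 0.6212, sd: 0.2549}
    120: {base: 0.5040, low: 0.4789, high: 0.5292, sd: 0.2835}
  sustained_pain: {base: 0.4400, low: 0.3740, high: 0.5020, sd: 0.2477}

psa:
  utility_sampling: independent  # or "shared": one utility draw used by both arms
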