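# Versioned regime presets for the two-state trajectory simulator.
# Probabilities are daily transition rates; see RegimeParams for semantics.
# Calibrated so that classifying the default simulated mix approximates
# the target 20/6/11/12 cohort split.
version: 1
regimes:
  constant_eubiotic:
    p_dysbiosis_menses: 0.01
    p_dysbiosis_spont: 0.001
    p_dysbiosis_intercourse: 0.005
    p_recover: 0.6
    start_dysbiotic: false
  menses_related_dysbiotic:
    p_dysbiosis_menses: 1.0
    p_dysbiosis_spont: 0.01
    p_dysbiosis_intercourse: 0.0
    p_recover: 0.5
    start_dysbiotic: false
  unstable:
    p_dysbiosis_menses: 0.6
    p_dysbiosis_spont: 0.24
    p_dysbiosis_intercourse: 0.55
    p_recover: 0.35
    start_dysbiotic: false
  constant_dysbiotic:
    p_dysbiosis_menses: 0.6
    p_dysbiosis_spont: 0.5
    p_dysbiosis_intercourse: 0.6
    p_recover: 0.02
    start_dysbiotic: true
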