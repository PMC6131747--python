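# CAM-S short form: the four diagnostic-algorithm features of the long form.
# Sum score range 0..7. Scored from the long-form calibration, not refit.
name: CAM-S-short
items:
  - {id: acute_onset_fluctuation, domain: acute_onset_fluctuation, categories: 2, cut: 1}
  - {id: inattention, domain: attention, categories: 3, cut: 1}
  - {id: disorganized_thinking, domain: disorganized_thinking, categories: 3, cut: 1}
  - {id: altered_consciousness, domain: consciousness, categories: 3, cut: 1}
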