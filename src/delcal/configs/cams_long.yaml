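# CAM-S long form: 9 features rated 0 (absent) / 1 (mild) / 2 (marked),
# plus acute onset or fluctuation rated 0/1. Sum score range 0..19.
name: CAM-S-long
items:
  - {id: acute_onset_fluctuation, domain: acute_onset_fluctuation, categories: 2, cut: 1}
  - {id: inattention, domain: attention, categories: 3, cut: 1}
  - {id: disorganized_thinking, domain: disorganized_thinking, categories: 3, cut: 1}
  - {id: altered_consciousness, domain: consciousness, categories: 3, cut: 1}
  - {id: disorientation, domain: orientation, categories: 3, cut: 1}
  - {id: memory_impairment, domain: memory, categories: 3, cut: 1}
  - {id: perceptual_disturbance, domain: perceptual_disturbance, categories: 3, cut: 1}
  - {id: psychomotor_agitation, domain: psychomotor_agitation, categories: 3, cut: 1}
  - {id: psychomotor_retardation, domain: psychomotor_retardation, categories: 3, cut: 1}
  - {id: sleep_wake_disturbance, domain: sleep_wake, categories: 3, cut: 2}
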