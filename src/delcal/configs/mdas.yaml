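# MDAS: 10 items rated 0..3. Sleep/wake disturbance dichotomized at cut 2.
name: MDAS
items:
  - {id: reduced_consciousness, domain: consciousness, categories: 4, cut: 1}
  - {id: disorientation, domain: orientation, categories: 4, cut: 1}
  - {id: short_term_memory, domain: memory, categories: 4, cut: 1}
  - {id: digit_span, domain: digit_span, categories: 4, cut: 1}
  - {id: attention, domain: attention, categories: 4, cut: 1}
  - {id: disorganized_thinking, domain: disorganized_thinking, categories: 4, cut: 1}
  - {id: perceptual_disturbance, domain: perceptual_disturbance, categories: 4, cut: 1}
  - {id: delusions, domain: delusions, categories: 4, cut: 1}
  - {id: psychomotor_activity, domain: psychomotor_activity, categories: 4, cut: 1}
  - {id: sleep_wake_disturbance, domain: sleep_wake, categories: 4, cut: 2}
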