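# DRS-R-98: 13 severity items, each rated 0 (not present) .. 3 (severe).
# Sleep/wake disturbance is dichotomized at moderate-or-worse (cut 2);
# every other item at any-symptom (cut 1).
name: DRS-R-98
items:
  - {id: sleep_wake_disturbance, domain: sleep_wake, categories: 4, cut: 2}
  - {id: perceptual_disturbance, domain: perceptual_disturbance, categories: 4, cut: 1}
  - {id: delusions, domain: delusions, categories: 4, cut: 1}
  - {id: lability_of_affect, domain: affect, categories: 4, cut: 1}
  - {id: language, domain: language, categories: 4, cut: 1}
  - {id: thought_process, domain: disorganized_thinking, categories: 4, cut: 1}
  - {id: motor_agitation, domain: psychomotor_agitation, categories: 4, cut: 1}
  - {id: motor_retardation, domain: psychomotor_retardation, categories: 4, cut: 1}
  - {id: orientation, domain: orientation, categories: 4, cut: 1}
  - {id: attention, domain: attention, categories: 4, cut: 1}
  - {id: short_term_memory, domain: memory, categories: 4, cut: 1}
  - {id: long_term_memory, domain: long_term_memory, categories: 4, cut: 1}
  - {id: visuospatial, domain: visuospatial, categories: 4, cut: 1}
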