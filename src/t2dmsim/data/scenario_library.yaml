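scenarios:
- name: who_action_plan
  factor_reductions:
    obesity: 0.0
    smoking: 0.3
    inactivity: 0.1
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_halt
  factor_reductions:
    obesity: 0.0
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_10
  factor_reductions:
    obesity: 0.1
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_20
  factor_reductions:
    obesity: 0.2
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_30
  factor_reductions:
    obesity: 0.3
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_40
  factor_reductions:
    obesity: 0.4
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_50
  factor_reductions:
    obesity: 0.5
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: smoking_halt
  factor_reductions:
    smoking: 0.0
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: smoking_minus_10
  factor_reductions:
    smoking: 0.1
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: smoking_minus_20
  factor_reductions:
    smoking: 0.2
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: smoking_minus_30
  factor_reductions:
    smoking: 0.3
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: smoking_minus_40
  factor_reductions:
    smoking: 0.4
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: smoking_minus_50
  factor_reductions:
    smoking: 0.5
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: inactivity_halt
  factor_reductions:
    inactivity: 0.0
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: inactivity_minus_10
  factor_reductions:
    inactivity: 0.1
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: inactivity_minus_20
  factor_reductions:
    inactivity: 0.2
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: inactivity_minus_30
  factor_reductions:
    inactivity: 0.3
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: inactivity_minus_40
  factor_reductions:
    inactivity: 0.4
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: inactivity_minus_50
  factor_reductions:
    inactivity: 0.5
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: combined_minus_50
  factor_reductions:
    obesity: 0.5
    smoking: 0.5
    inactivity: 0.5
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: pa_vigorous
  factor_reductions: {}
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: vigorous
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: pa_low
  factor_reductions: {}
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: low
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: pa_moderate
  factor_reductions: {}
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: moderate
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: pa_leisure
  factor_reductions: {}
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: leisure
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: pa_walking
  factor_reductions: {}
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: walking
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: combined_minus_50_pa_vigorous
  factor_reductions:
    obesity: 0.5
    smoking: 0.5
    inactivity: 0.5
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: vigorous
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_40_ramp5y
  factor_reductions:
    obesity: 0.4
  ramp_start: 2016.0
  ramp_end: 2021.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_40_ramp10y
  factor_reductions:
    obesity: 0.4
  ramp_start: 2016.0
  ramp_end: 2026.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_40_ramp15y
  factor_reductions:
    obesity: 0.4
  ramp_start: 2016.0
  ramp_end: 2031.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
- name: obesity_minus_40_ramp20y
  factor_reductions:
    obesity: 0.4
  ramp_start: 2016.0
  ramp_end: 2036.0
  hold_until: 2050.0
  pa_intensity: null
  pa_coverage: 0.25
  target_bands:
  - 3
  - 12
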