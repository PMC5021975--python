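# Two-institution synthetic cohort: shared seasonal effects + null conditions.
population:
  n_patients: 50000
  birth_year_range: [1926, 2000]
  demographics:
    - name: sex
      categories: [female, male, other]
      probs: [0.58, 0.4197, 0.0003]
effects:
  - condition_code: coronary-arteriosclerosis
    prevalence_p0: 0.06
    amplitude_A: 0.07
    peak_month_phi: 1
  - condition_code: essential-hypertension
    prevalence_p0: 0.15
    amplitude_A: 0.03
    peak_month_phi: 1
null_conditions: 10
mode: shared          # shared | independent | null
labels: [site_a, site_b]
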