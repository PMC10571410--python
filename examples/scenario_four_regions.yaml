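# Four synthetic regions shaped like a large multi-regional survey of
# personality-disorder care: three large regions and one small province.
# Cohort sizes are fixed (n_prevalent / n_newly); per-region probabilities
# are the true per-patient marginals of the matching indicators.  Any
# RegionScenario field may be set here; omitted fields keep their defaults.
- region: north-a
  seed: 0
  n_adults: 8305641
  prevalence_per_10k: 19.5
  incidence_per_10k: 3.4
  n_prevalent: 16196
  n_newly: 883
  p_contact: 0.923
  contact_rate: 8.0
  p_psychiatric_visit: 0.817
  p_psychosocial: 0.524
  p_psychotherapy: 0.207
  p_antipsychotic: 0.487
  p_vpa_cbz: 0.168
  p_residential: 0.175
  p_ghpw_admission: 0.142
  p_community_persistent: 0.688
- region: north-b
  seed: 0
  icd_dialect: icd9cm
  n_adults: 3740316
  prevalence_per_10k: 25.3
  incidence_per_10k: 5.5
  n_prevalent: 9462
  n_newly: 609
  p_contact: 0.984
  contact_rate: 13.0
  p_psychiatric_visit: 0.839
  p_psychosocial: 0.515
  p_psychotherapy: 0.095
  p_antipsychotic: 0.566
  p_vpa_cbz: 0.180
  p_residential: 0.168
  p_ghpw_admission: 0.124
  p_community_persistent: 0.584
  unavailable_services: [home]
- region: island
  seed: 0
  n_adults: 1037778
  prevalence_per_10k: 9.0
  incidence_per_10k: 2.8
  n_prevalent: 934
  n_newly: 106
  p_contact: 0.742
  contact_rate: 7.0
  p_psychiatric_visit: 0.651
  p_psychosocial: 0.526
  p_psychotherapy: 0.197
  p_antipsychotic: 0.328
  p_vpa_cbz: 0.263
  p_residential: 0.020
  p_ghpw_admission: 0.122
  p_community_persistent: 0.332
- region: centre
  seed: 0
  n_adults: 4900000
  prevalence_per_10k: 10.4
  incidence_per_10k: 4.7
  n_prevalent: 5096
  n_newly: 733
  p_contact: 0.974
  contact_rate: 10.0
  p_psychiatric_visit: 0.765
  p_psychosocial: 0.590
  p_psychotherapy: 0.324
  p_antipsychotic: 0.392
  p_vpa_cbz: 0.228
  p_residential: 0.102
  p_ghpw_admission: 0.086
  p_community_persistent: 0.471
  unavailable_services: [psychoeducation]
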