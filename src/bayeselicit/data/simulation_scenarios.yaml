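# Data-simulation scenarios for the operating-characteristics study.
# mu_P_mm / mu_A_mm are the true long-run average changes from baseline in
# pain score (mm, negative = improvement) on pamidronate / adalimumab;
# sigma_mm is the common outcome standard deviation. In each block the first
# case has no treatment difference and the second puts pamidronate ahead by
# exactly the 30% clinically relevant margin (mu_A = mu_P / 1.3).
scenarios:
  - label: A_null
    mu_P_mm: -32.3
    mu_A_mm: -32.3
    sigma_mm: 9.3
    n_per_arm: 20
  - label: A_effect
    mu_P_mm: -32.3
    mu_A_mm: -24.9
    sigma_mm: 9.3
    n_per_arm: 20
  - label: B_null
    mu_P_mm: -40.0
    mu_A_mm: -40.0
    sigma_mm: 11.5
    n_per_arm: 20
  - label: B_effect
    mu_P_mm: -40.0
    mu_A_mm: -30.8
    sigma_mm: 11.5
    n_per_arm: 20
  - label: C_null
    mu_P_mm: -26.0
    mu_A_mm: -26.0
    sigma_mm: 7.5
    n_per_arm: 20
  - label: C_effect
    mu_P_mm: -26.0
    mu_A_mm: -20.0
    sigma_mm: 7.5
    n_per_arm: 20
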