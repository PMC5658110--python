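# Bundled cohort scenario for the lifetime rTMS vs. pharmacotherapy model.
# Values marked "(printed)" in source_note pin figures printed in the source
# analysis (Medicare $206/session, $372.50/month drug supply, 25.3 sessions/yr,
# 3% discount, cohort life expectancies, $9,140/yr other direct costs).
# Everything marked "reconstruction" is a documented plausible default standing
# in for unpublished appendix values -- NOT a published estimate.
cohort: mid-40s
life_expectancy:
  likely: 28
  low: 13
  high: 43
discount_rate: 0.03
wtp: 0.0
include_background_mortality: true
half_cycle_correction: false
relapse_reentry_attempt: 1
parameters:
  attenuation_pharma:
    role: probability
    base: 0.75
    low: 0.55
    high: 0.95
    units: factor/failed attempt
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 13.312500000000007
      - 4.437500000000003
  attenuation_rtms:
    role: probability
    base: 0.8
    low: 0.6
    high: 1.0
    units: factor/failed attempt
    source_note: diminished success per prior failure; reconstruction
    distribution:
      family: beta
      parameters:
      - 11.999999999999996
      - 2.9999999999999982
  cost_per_rtms_session:
    role: cost
    base: 206.0
    low: 100.0
    high: 300.0
    units: USD/session
    source_note: CPT 90868; 2016 national average Medicare rate $206/session (printed)
    distribution:
      family: gamma
      parameters:
      - 16.9744
      - 12.135922330097088
  cost_rtms_initial_session:
    role: cost
    base: 250.0
    low: 150.0
    high: 350.0
    units: USD
    source_note: CPT 90867 initial session incl. motor threshold; reconstruction
    distribution:
      family: gamma
      parameters:
      - 25.0
      - 10.0
  cost_rtms_mt_redetermination:
    role: cost
    base: 60.0
    low: 30.0
    high: 120.0
    units: USD
    source_note: CPT 90869; reconstruction
    distribution:
      family: gamma
      parameters:
      - 7.111111111111111
      - 8.4375
  drug_cost_monthly:
    role: cost
    base: 372.5
    low: 100.0
    high: 450.0
    units: USD/month
    source_note: antidepressant supply $372.50/month (printed); $100 generic low
    distribution:
      family: gamma
      parameters:
      - 18.12326530612245
      - 20.553691275167786
  ect_course_cost_annual:
    role: cost
    base: 10000.0
    low: 7000.0
    high: 15000.0
    units: USD/year
    source_note: annual ECT course; reconstruction from literature rates
    distribution:
      family: gamma
      parameters:
      - 25.0
      - 400.0
  other_direct_annual:
    role: cost
    base: 9140.0
    low: 8500.0
    high: 9800.0
    units: USD/year
    source_note: non-depression drugs $1,440 + non-mental-health visits $7,700 (printed);
      common to both arms
    distribution:
      family: gamma
      parameters:
      - 790.9074556213018
      - 11.556345733041576
  p_remission_ect:
    role: probability
    base: 0.5
    low: 0.3
    high: 0.7
    units: per year
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 12.000000000000002
      - 12.000000000000002
  p_remission_pharma:
    role: probability
    base: 0.25
    low: 0.15
    high: 0.4
    units: per attempt-year
    source_note: reconstruction (post one failed trial)
    distribution:
      family: beta
      parameters:
      - 11.75
      - 35.25
  p_remission_rtms:
    role: probability
    base: 0.35
    low: 0.2
    high: 0.5
    units: per attempt-year
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 13.805555555555554
      - 25.63888888888889
  p_response_pharma:
    role: probability
    base: 0.2
    low: 0.1
    high: 0.3
    units: per attempt-year
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 12.600000000000007
      - 50.40000000000003
  p_response_rtms:
    role: probability
    base: 0.25
    low: 0.15
    high: 0.35
    units: per attempt-year
    source_note: reconstruction (response without remission)
    distribution:
      family: beta
      parameters:
      - 18.500000000000004
      - 55.500000000000014
  psychotherapy_session_rate:
    role: cost
    base: 85.0
    low: 60.0
    high: 120.0
    units: USD/session
    source_note: 2016 Medicare psychotherapy rate; reconstruction
    distribution:
      family: gamma
      parameters:
      - 32.111111111111114
      - 2.6470588235294117
  psychotherapy_sessions_per_year:
    role: count
    base: 12.0
    low: 6.0
    high: 24.0
    units: sessions/year
    source_note: reconstruction
    distribution:
      family: gamma
      parameters:
      - 7.111111111111111
      - 1.6875
  relapse_annual_pharma:
    role: probability
    base: 0.3
    low: 0.15
    high: 0.45
    units: per year
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 10.899999999999997
      - 25.433333333333323
  relapse_annual_rtms:
    role: probability
    base: 0.25
    low: 0.1
    high: 0.4
    units: per year
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 8.08333333333333
      - 24.249999999999993
  rtms_mt_redeterminations_per_year:
    role: count
    base: 1.0
    low: 0.0
    high: 4.0
    units: per year
    source_note: reconstruction
    distribution:
      family: gamma
      parameters:
      - 1.0
      - 1.0
  rtms_sessions_per_year:
    role: count
    base: 25.3
    low: 8.0
    high: 43.0
    units: sessions/year
    source_note: 25.3 +/- 16.7 sessions, range 8-43 (printed)
    distribution:
      family: gamma
      parameters:
      - 8.36035918367347
      - 3.0261857707509883
  utility_ect:
    role: utility
    base: 0.55
    low: 0.45
    high: 0.65
    units: Euro-QoL index
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 53.9
      - 44.09999999999999
  utility_in_treatment:
    role: utility
    base: 0.58
    low: 0.48
    high: 0.68
    units: Euro-QoL index
    source_note: depressed, in active treatment; reconstruction
    distribution:
      family: beta
      parameters:
      - 55.93519999999996
      - 40.50479999999998
  utility_nonresponse:
    role: utility
    base: 0.5
    low: 0.4
    high: 0.6
    units: Euro-QoL index
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 49.50000000000003
      - 49.50000000000003
  utility_relapse:
    role: utility
    base: 0.55
    low: 0.45
    high: 0.65
    units: Euro-QoL index
    source_note: relapse requiring re-treatment; reconstruction
    distribution:
      family: beta
      parameters:
      - 53.9
      - 44.09999999999999
  utility_remission:
    role: utility
    base: 0.85
    low: 0.75
    high: 0.95
    units: Euro-QoL index
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 42.50000000000002
      - 7.500000000000005
  utility_response:
    role: utility
    base: 0.72
    low: 0.62
    high: 0.82
    units: Euro-QoL index
    source_note: reconstruction
    distribution:
      family: beta
      parameters:
      - 57.34080000000003
      - 22.299200000000013
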