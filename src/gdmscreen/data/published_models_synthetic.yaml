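# SYNTHETIC stand-in coefficients for the four published first-trimester
# GDM prognostic models (Gabbay-Benziv 2014, Nanda 2011, Teede 2011,
# van Leeuwen 2010).
#
# The original full equations live in supplementary material that is not
# redistributable here, so these coefficients are NOT the published ones:
# they are plausible-magnitude placeholders with the correct predictor set
# per model and the published effect directions. The analysis pipeline
# recalibrates every model (slope + intercept) on the cohort before any
# comparison, so results depend on each model's predictor set and risk
# ranking, not on these magnitudes. Replace this file with a verbatim
# transcription of the published equations to score the real models.
#
# Category reference levels: ethnicity=caucasian (indicators for the other
# levels), i.e. a caucasian subject contributes 0 from ethnicity terms.

models:
  - name: gabbay_benziv_2014
    intercept: -9.4
    terms:
      - {predictor: age_years, transform: identity, coefficient: 0.04}
      - {predictor: bmi, transform: identity, coefficient: 0.09}
      - {predictor: sbp_mmhg, transform: identity, coefficient: 0.015}
      - {predictor: history_gdm, transform: identity, coefficient: 2.2}
      - {predictor: ethnicity, transform: indicator, level: asian, coefficient: 1.0}
      - {predictor: ethnicity, transform: indicator, level: african, coefficient: 0.5}
      - {predictor: ethnicity, transform: indicator, level: mixed, coefficient: 0.2}
      - {predictor: ethnicity, transform: indicator, level: other, coefficient: 0.6}

  - name: nanda_2011
    intercept: -7.9
    terms:
      - {predictor: age_years, transform: identity, coefficient: 0.05}
      - {predictor: bmi, transform: identity, coefficient: 0.10}
      - {predictor: history_gdm, transform: identity, coefficient: 2.4}
      - {predictor: history_macrosomia, transform: identity, coefficient: 0.7}
      - {predictor: parity, transform: identity, coefficient: -0.15}
      - {predictor: ethnicity, transform: indicator, level: asian, coefficient: 1.1}
      - {predictor: ethnicity, transform: indicator, level: african, coefficient: 0.4}
      - {predictor: ethnicity, transform: indicator, level: mixed, coefficient: 0.3}
      - {predictor: ethnicity, transform: indicator, level: other, coefficient: 0.7}

  - name: teede_2011
    intercept: -8.3
    terms:
      - {predictor: age_years, transform: identity, coefficient: 0.06}
      - {predictor: bmi, transform: identity, coefficient: 0.10}
      - {predictor: history_gdm, transform: identity, coefficient: 2.3}
      - {predictor: family_history_dm, transform: identity, coefficient: 0.8}
      - {predictor: ethnicity, transform: indicator, level: asian, coefficient: 1.2}
      - {predictor: ethnicity, transform: indicator, level: african, coefficient: 0.5}
      - {predictor: ethnicity, transform: indicator, level: mixed, coefficient: 0.3}
      - {predictor: ethnicity, transform: indicator, level: other, coefficient: 0.7}

  - name: van_leeuwen_2010
    intercept: -6.2
    terms:
      - {predictor: bmi, transform: identity, coefficient: 0.09}
      - {predictor: history_gdm, transform: identity, coefficient: 2.3}
      - {predictor: family_history_dm, transform: identity, coefficient: 0.7}
      - {predictor: parity, transform: identity, coefficient: 0.1}
      - {predictor: ethnicity, transform: indicator, level: asian, coefficient: 1.1}
      - {predictor: ethnicity, transform: indicator, level: african, coefficient: 0.4}
      - {predictor: ethnicity, transform: indicator, level: mixed, coefficient: 0.2}
      - {predictor: ethnicity, transform: indicator, level: other, coefficient: 0.6}

reference_method:
  bmi_cutoff: 30.0
  bmi_strict: true
  high_prevalence_ethnicities: [asian, other]
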