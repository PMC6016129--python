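# Default cause list and relative-risk specification.
#
# Provenance: the cause set spans the alcohol-attributable causes of death
# used in comparative risk assessments (communicable: HIV/AIDS, tuberculosis,
# lower respiratory infections; non-communicable: alcohol-related cancers,
# cardiometabolic and digestive diseases, epilepsy; and all injuries).
# The curve coefficients are PLACEHOLDERS of plausible magnitude patterned
# on the dose-response meta-analytic literature; they are configuration,
# meant to be replaced with a vetted coefficient set for any substantive use.
#
# Curves give ln RR(x) at x grams of pure alcohol/day:
#   polynomial:       ln RR = sum_k coefficients[k] * x^(k+1)   (RR(0)=1 forced)
#   piecewise_linear: ln RR linearly interpolated between knots; first knot
#                     must be [0, 0].
# binge_protection_lost: for drinkers classified as binge drinkers the RR is
#   floored at 1 (any protective dip removed).
# ses_interaction: multiplicative modifier on the current-drinker RR by SES
#   level (levels not listed default to 1).
lower_gpd: 0.1
cap_gpd: 150.0
causes:
  - cause: hiv_aids
    broader_category: infectious
    curve: {type: polynomial, coefficients: [0.0040], se: [0.0010]}
    rr_former: {value: 1.20, ci: [1.00, 1.44]}
    ses_interaction: {low: 1.5}
  - cause: tuberculosis
    broader_category: infectious
    curve: {type: polynomial, coefficients: [0.0120], se: [0.0025]}
    rr_former: {value: 1.30, ci: [1.05, 1.61]}
  - cause: lower_respiratory_infections
    broader_category: infectious
    curve: {type: polynomial, coefficients: [0.0050], se: [0.0012]}
    rr_former: {value: 1.15, ci: [0.95, 1.39]}
  - cause: oral_cavity_pharynx_cancer
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0130], se: [0.0020]}
    rr_former: {value: 1.40, ci: [1.10, 1.78]}
  - cause: oesophagus_cancer
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0100], se: [0.0018]}
    rr_former: {value: 1.30, ci: [1.05, 1.61]}
  - cause: liver_cancer
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0080], se: [0.0016]}
    rr_former: {value: 1.30, ci: [1.02, 1.66]}
  - cause: larynx_cancer
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0120], se: [0.0022]}
    rr_former: {value: 1.35, ci: [1.06, 1.72]}
  - cause: breast_cancer
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0100], se: [0.0015]}
    rr_former: {value: 1.10, ci: [0.95, 1.27]}
  - cause: diabetes_mellitus
    broader_category: chronic
    curve: {type: polynomial, coefficients: [-0.0100, 0.00012], se: [0.0030, 0.00004]}
    rr_former: {value: 1.15, ci: [0.92, 1.44]}
    binge_protection_lost: true
  - cause: epilepsy
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0120], se: [0.0030]}
    rr_former: {value: 1.20, ci: [0.90, 1.60]}
  - cause: hypertensive_heart_disease
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0090], se: [0.0020]}
    rr_former: {value: 1.10, ci: [0.90, 1.34]}
  - cause: ischemic_heart_disease
    broader_category: chronic
    curve: {type: polynomial, coefficients: [-0.0120, 0.00012], se: [0.0030, 0.00004]}
    rr_former: {value: 1.15, ci: [0.95, 1.39]}
    binge_protection_lost: true
  - cause: ischemic_stroke
    broader_category: chronic
    curve: {type: polynomial, coefficients: [-0.0080, 0.00012], se: [0.0025, 0.00004]}
    rr_former: {value: 1.10, ci: [0.90, 1.34]}
    binge_protection_lost: true
  - cause: hemorrhagic_stroke
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0070], se: [0.0018]}
    rr_former: {value: 1.15, ci: [0.92, 1.44]}
  - cause: liver_cirrhosis
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0200], se: [0.0030]}
    rr_former: {value: 1.40, ci: [1.10, 1.78]}
  - cause: pancreatitis
    broader_category: chronic
    curve: {type: polynomial, coefficients: [0.0040, 0.00015], se: [0.0015, 0.00005]}
    rr_former: {value: 1.25, ci: [0.95, 1.64]}
  - cause: road_injuries
    broader_category: injuries
    curve: {type: polynomial, coefficients: [0.0080], se: [0.0018]}
    rr_former: {value: 1.00, ci: [1.00, 1.00]}
  - cause: intentional_injuries
    broader_category: injuries
    curve: {type: polynomial, coefficients: [0.0090], se: [0.0020]}
    rr_former: {value: 1.00, ci: [1.00, 1.00]}
  - cause: other_unintentional_injuries
    broader_category: injuries
    curve: {type: polynomial, coefficients: [0.0080], se: [0.0018]}
    rr_former: {value: 1.00, ci: [1.00, 1.00]}
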