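# Default synthetic-cohort configuration.
#
# The conditional tables reproduce the published prevalence structure of a
# GP-classified cohort aged 75+: frailty margins by age class and by gender,
# hospitalization and multi-morbidity rates per frailty status, and the named
# multi-morbidity profile rates (all expressed as probabilities, not %).
#
# Distributions the published margins do not determine (joint age x gender,
# marital/family status conditionals, single-category disease weights, toy
# ICD-9-CM code lists) are calibrated stand-ins chosen to reproduce the
# qualitative associations between frailty, widowhood, living arrangement and
# injury/poisoning hospitalizations.  They are configuration, not estimates.

p_gender:
  Male: 0.403
  Female: 0.597

# Mixing these over p_gender yields the age marginal [0.40, 0.30, 0.20, 0.10],
# which is consistent with the frailty-by-age and overall frailty margins
# below; women skew older than men.
p_age_given_gender:
  Male:   {"75-79": 0.4600, "80-84": 0.3000, "85-89": 0.1700, "90+": 0.0700}
  Female: {"75-79": 0.3595, "80-84": 0.3000, "85-89": 0.2202, "90+": 0.1203}

p_frailty_given_age:
  "75-79": {NF: 0.833, PFSN: 0.047, PFHN: 0.080, FR: 0.039}
  "80-84": {NF: 0.696, PFSN: 0.050, PFHN: 0.166, FR: 0.089}
  "85-89": {NF: 0.513, PFSN: 0.045, PFHN: 0.299, FR: 0.143}
  "90+":   {NF: 0.314, PFSN: 0.028, PFHN: 0.462, FR: 0.196}

p_frailty_given_gender:
  Male:   {NF: 0.749, PFSN: 0.047, PFHN: 0.140, FR: 0.064}
  Female: {NF: 0.625, PFSN: 0.045, PFHN: 0.221, FR: 0.109}

p_frailty_overall: {NF: 0.675, PFSN: 0.046, PFHN: 0.188, FR: 0.091}

# Probability of >=1 hospital admission in the 12 months before the index
# date, per frailty status.
p_hosp_given_frailty: {NF: 0.142, PFSN: 0.157, PFHN: 0.229, FR: 0.235}

# Share of each frailty status carrying a multi-morbid profile (>=2 clinical
# categories).  The rate conditional on hospitalization is derived as
# p_multimorbid_given_frailty / p_hosp_given_frailty.
p_multimorbid_given_frailty: {NF: 0.067, PFSN: 0.096, PFHN: 0.130, FR: 0.144}

# Calibrated stand-ins: frail / socially pre-frail elderly skew toward
# widowhood, living alone and institutionalization; the not-frail toward
# marriage and non-critical family settings.
p_marital_given_frailty_gender:
  NF:
    Male:   {Married: 0.78, Unmarried: 0.07, Widowed: 0.15}
    Female: {Married: 0.52, Unmarried: 0.08, Widowed: 0.40}
  PFSN:
    Male:   {Married: 0.35, Unmarried: 0.15, Widowed: 0.50}
    Female: {Married: 0.15, Unmarried: 0.12, Widowed: 0.73}
  PFHN:
    Male:   {Married: 0.60, Unmarried: 0.08, Widowed: 0.32}
    Female: {Married: 0.35, Unmarried: 0.08, Widowed: 0.57}
  FR:
    Male:   {Married: 0.40, Unmarried: 0.10, Widowed: 0.50}
    Female: {Married: 0.15, Unmarried: 0.10, Widowed: 0.75}

p_family_given_frailty_gender:
  NF:
    Male:   {NoCriticalFamily: 0.550, ElderlyCouple: 0.320, ElderlyCaregiver: 0.090, LivingAlone: 0.035, ElderlyInstitutionalized: 0.005}
    Female: {NoCriticalFamily: 0.500, ElderlyCouple: 0.300, ElderlyCaregiver: 0.100, LivingAlone: 0.090, ElderlyInstitutionalized: 0.010}
  PFSN:
    Male:   {NoCriticalFamily: 0.100, ElderlyCouple: 0.080, ElderlyCaregiver: 0.020, LivingAlone: 0.550, ElderlyInstitutionalized: 0.250}
    Female: {NoCriticalFamily: 0.080, ElderlyCouple: 0.050, ElderlyCaregiver: 0.020, LivingAlone: 0.580, ElderlyInstitutionalized: 0.270}
  PFHN:
    Male:   {NoCriticalFamily: 0.380, ElderlyCouple: 0.250, ElderlyCaregiver: 0.070, LivingAlone: 0.220, ElderlyInstitutionalized: 0.080}
    Female: {NoCriticalFamily: 0.320, ElderlyCouple: 0.220, ElderlyCaregiver: 0.060, LivingAlone: 0.280, ElderlyInstitutionalized: 0.120}
  FR:
    Male:   {NoCriticalFamily: 0.120, ElderlyCouple: 0.100, ElderlyCaregiver: 0.030, LivingAlone: 0.450, ElderlyInstitutionalized: 0.300}
    Female: {NoCriticalFamily: 0.100, ElderlyCouple: 0.060, ElderlyCaregiver: 0.020, LivingAlone: 0.470, ElderlyInstitutionalized: 0.350}

# Named multi-morbidity profile rates as probabilities over the whole status
# population (the residual "Other" entry closes the multi-morbidity budget).
# Within the generator they are renormalized to a categorical distribution
# conditional on being multi-morbid.
profile_weights:
  NF:   [0.005, 0.003, 0.004, 0.002, 0.002, 0.001, 0.002, 0.002, 0.002, 0.001, 0.001, 0.001, 0.001, 0.001, 0.001, 0.038]
  PFSN: [0.007, 0.003, 0.004, 0.002, 0.004, 0.005, 0.003, 0.001, 0.003, 0.002, 0.005, 0.000, 0.005, 0.002, 0.000, 0.052]
  PFHN: [0.008, 0.006, 0.003, 0.005, 0.003, 0.002, 0.002, 0.002, 0.001, 0.002, 0.001, 0.002, 0.001, 0.001, 0.000, 0.090]
  FR:   [0.011, 0.005, 0.002, 0.002, 0.006, 0.003, 0.003, 0.001, 0.000, 0.001, 0.003, 0.002, 0.002, 0.003, 0.002, 0.097]

# Size distribution of unnamed ("other") multi-morbid category sets.
other_profile_size_probs: {2: 0.60, 3: 0.30, 4: 0.10}

# Single-category weights for hospitalized patients that are not multi-morbid.
# The override channels injury/poisoning admissions toward socially frail
# women, mirroring the dominance of injury-and-poisoning single-diagnosis
# profiles in that stratum.
single_category_weights:
  base:
    Circulatory: 0.20
    Respiratory: 0.10
    Digestive: 0.09
    InjuryPoisoning: 0.08
    EndocrineMetabolic: 0.08
    Neoplasms: 0.08
    GenitoUrinary: 0.07
    Nervous: 0.06
    Musculoskeletal: 0.06
    MentalIllness: 0.05
    SignsSymptoms: 0.05
    Blood: 0.03
    Infectious: 0.03
    Skin: 0.02
  overrides:
    - {frailty: PFSN, gender: Female, category: InjuryPoisoning, weight: 0.55}
    - {frailty: FR,   gender: Female, category: InjuryPoisoning, weight: 0.55}

# Toy ICD-9-CM three-digit roots per clinical category (stand-in for licensed
# grouper tables; the mapping layer accepts any root->category file).
codes_per_category:
  InjuryPoisoning: ["820", "850", "965"]
  Blood: ["280", "285"]
  Circulatory: ["401", "410", "427", "428"]
  Digestive: ["531", "571", "574"]
  EndocrineMetabolic: ["250", "272", "276"]
  GenitoUrinary: ["584", "590", "600"]
  Infectious: ["003", "038", "070"]
  MentalIllness: ["290", "296", "300"]
  Musculoskeletal: ["715", "721", "733"]
  Neoplasms: ["153", "162", "174", "185"]
  Nervous: ["331", "332", "365", "389"]
  Respiratory: ["480", "486", "491", "496"]
  Skin: ["680", "682", "707"]
  SignsSymptoms: ["780", "786", "799"]

# Reference window: discharges are drawn uniformly over the 365 days
# preceding the index date (half-open window [index - 365 d, index)).
index_date: "2007-01-01"
window_days: 365

# One discharge per hospitalized patient by default; the analysis only uses
# presence/absence of each category.
discharges_per_patient: 1
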