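"""Shared fixture data: the published example sentences for each phenotype
concept, with the assertion/category their row label assigns.

CATEGORICAL_EXAMPLES rows: (sentence, concept_id, expected_assertion, expected_label)
NUMERIC_EXAMPLES rows: (sentence, concept_id, expected_value, canonical_unit)
"""

CATEGORICAL_EXAMPLES = [
    ("Findings consistent with hypertrophic cardiomyopathy",
     "HCM_DIAGNOSIS", "ASSERTED", None),
    ("There is no evidence for hypertrophic cardiomyopathy",
     "HCM_DIAGNOSIS", "NEGATED", None),
    ("Consistent with sigmoid morphologic subtype of hypertrophic obstructive cardiomyopathy",
     "HCM_SUBTYPE", "ASSERTED", "SIGMOID"),
    ("Consistent with reverse curve morphologic subtype hypertrophic cardiomyopathy",
     "HCM_SUBTYPE", "ASSERTED", "REVERSE_CURVE"),
    ("Hypertrophic obstructive cardiomyopathy, neutral subtype",
     "HCM_SUBTYPE", "ASSERTED", "NEUTRAL"),
    ("Hypertrophic cardiomyopathy, apical morphologic subtype",
     "HCM_SUBTYPE", "ASSERTED", "APICAL"),
    ("Systolic anterior motion of the mitral valve is present",
     "SAM", "ASSERTED", None),
    ("No systolic anterior motion of the mitral valve",
     "SAM", "NEGATED", None),
    ("Mitral regurgitation is present",
     "MITRAL_REGURGITATION", "ASSERTED", None),
    ("No mitral regurgitation seen",
     "MITRAL_REGURGITATION", "NEGATED", None),
    ("There is turbulent flow in the left ventricular outflow tract",
     "LV_OBSTRUCTION", "ASSERTED", None),
    ("No turbulence is seen in the LV outflow tract",
     "LV_OBSTRUCTION", "NEGATED", None),
    ("There is turbulent flow in the left ventricular outflow tract",
     "OBSTRUCTION_LOCATION", "ASSERTED", "LVOT"),
    ("Turbulent flow is present in the mid chamber",
     "OBSTRUCTION_LOCATION", "ASSERTED", "MID_VENTRICULAR"),
    ("A small apical pouch is noted",
     "APICAL_POUCH", "ASSERTED", None),
    ("No evidence of apical pouch",
     "APICAL_POUCH", "NEGATED", None),
    ("Delayed myocardial enhancement within the left ventricular apex",
     "LV_DELAYED_ENHANCEMENT", "ASSERTED", None),
    ("Delayed myocardial enhancement is not present",
     "LV_DELAYED_ENHANCEMENT", "NEGATED", None),
    ("Enlarged left atrium",
     "LA_ENLARGEMENT", "ASSERTED", None),
    ("No significant left atrial enlargement",
     "LA_ENLARGEMENT", "NEGATED", None),
    ("Right atrial enlargement",
     "RA_ENLARGEMENT", "ASSERTED", None),
    ("No significant right atrial enlargement",
     "RA_ENLARGEMENT", "NEGATED", None),
]

NUMERIC_EXAMPLES = [
    ("The maximal thickness of the myocardium measured in diastole is 22 mm",
     "MAX_LV_WALL_THICKNESS", 22.0, "mm"),
    ("LV End Diastolic Mass = 426 g", "LV_MASS", 426.0, "g"),
    ("LV End Diastolic Mass Index = 186 g/m2", "LV_MASS_INDEX", 186.0, "g/m2"),
    ("Hyperdynamic left ventricular ejection fraction; 83%", "LV_EF", 83.0, "%"),
    ("RV Ejection Fraction: 61%", "RV_EF", 61.0, "%"),
]
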