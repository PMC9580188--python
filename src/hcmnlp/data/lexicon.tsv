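# Default concept lexicon.  Tab-delimited: concept_id, pattern, pattern_type, role, label
# pattern_type: literal | regex.  Literals match case-insensitively on word
# boundaries with flexible internal whitespace.  role: target | negation_cue |
# hedge_cue | pseudo_negation | termination.  Cue rows with concept_id ALL
# apply to every concept.  label is used only by multiclass target patterns.
#
# --- tier 1: diagnosis -----------------------------------------------------
HCM_DIAGNOSIS	hypertrophic cardiomyopathy	literal	target
HCM_DIAGNOSIS	hypertrophic obstructive cardiomyopathy	literal	target
HCM_DIAGNOSIS	HCM	literal	target
HCM_DIAGNOSIS	HOCM	literal	target
HCM_DIAGNOSIS	asymmetric septal hypertrophy	literal	target
HCM_DIAGNOSIS	asymmetrical septal hypertrophy	literal	target
HCM_DIAGNOSIS	ASH	literal	target
# --- morphologic subtype (multiclass) --------------------------------------
HCM_SUBTYPE	sigmoid(?: morphologic| septal)? (?:sub)?type	regex	target	SIGMOID
HCM_SUBTYPE	reverse[- ]curv(?:e|ature)(?: morphologic| septal)? (?:sub)?type	regex	target	REVERSE_CURVE
HCM_SUBTYPE	neutral(?: morphologic| septal)? (?:sub)?type	regex	target	NEUTRAL
HCM_SUBTYPE	apical(?: morphologic| septal)? (?:sub)?type	regex	target	APICAL
HCM_SUBTYPE	apical variant	literal	target	APICAL
# --- systolic anterior motion ----------------------------------------------
SAM	systolic anterior motion of the mitral valve	literal	target
SAM	systolic anterior motion	literal	target
SAM	SAM	literal	target
# --- mitral regurgitation ---------------------------------------------------
MITRAL_REGURGITATION	mitral regurgitation	literal	target
MITRAL_REGURGITATION	mitral valve regurgitation	literal	target
MITRAL_REGURGITATION	mitral insufficiency	literal	target
# --- LV obstruction ----------------------------------------------------------
LV_OBSTRUCTION	turbulent flow	literal	target
LV_OBSTRUCTION	turbulence	literal	target
LV_OBSTRUCTION	flow acceleration	literal	target
LV_OBSTRUCTION	outflow tract obstruction	literal	target
LV_OBSTRUCTION	outflow obstruction	literal	target
LV_OBSTRUCTION	LVOT obstruction	literal	target
LV_OBSTRUCTION	subaortic obstruction	literal	target
LV_OBSTRUCTION	hypertrophic obstructive cardiomyopathy	literal	target
# --- obstruction location (multiclass) ---------------------------------------
OBSTRUCTION_LOCATION	left ventricular outflow tract	literal	target	LVOT
OBSTRUCTION_LOCATION	LV outflow tract	literal	target	LVOT
OBSTRUCTION_LOCATION	outflow tract	literal	target	LVOT
OBSTRUCTION_LOCATION	LVOT	literal	target	LVOT
OBSTRUCTION_LOCATION	mid chamber	literal	target	MID_VENTRICULAR
OBSTRUCTION_LOCATION	mid[- ]?ventricular	regex	target	MID_VENTRICULAR
OBSTRUCTION_LOCATION	mid[- ]?cavit(?:y|ary)	regex	target	MID_VENTRICULAR
# --- apical pouch ------------------------------------------------------------
APICAL_POUCH	apical pouch	literal	target
APICAL_POUCH	apical outpouching	literal	target
# --- LV delayed enhancement --------------------------------------------------
LV_DELAYED_ENHANCEMENT	delayed myocardial enhancement	literal	target
LV_DELAYED_ENHANCEMENT	delayed enhancement	literal	target
LV_DELAYED_ENHANCEMENT	delayed hyperenhancement	literal	target
LV_DELAYED_ENHANCEMENT	delayed gadolinium enhancement	literal	target
LV_DELAYED_ENHANCEMENT	late gadolinium enhancement	literal	target
LV_DELAYED_ENHANCEMENT	late enhancement	literal	target
LV_DELAYED_ENHANCEMENT	LGE	literal	target
# --- left atrial enlargement -------------------------------------------------
LA_ENLARGEMENT	enlarged left atrium	literal	target
LA_ENLARGEMENT	left atrial enlargement	literal	target
LA_ENLARGEMENT	dilated left atrium	literal	target
LA_ENLARGEMENT	left atrial dilatation	literal	target
LA_ENLARGEMENT	left atrial dilation	literal	target
LA_ENLARGEMENT	left atrium is (?:mildly |moderately |severely )?(?:enlarged|dilated)	regex	target
# --- right atrial enlargement ------------------------------------------------
RA_ENLARGEMENT	enlarged right atrium	literal	target
RA_ENLARGEMENT	right atrial enlargement	literal	target
RA_ENLARGEMENT	dilated right atrium	literal	target
RA_ENLARGEMENT	right atrial dilatation	literal	target
RA_ENLARGEMENT	right atrial dilation	literal	target
RA_ENLARGEMENT	right atrium is (?:mildly |moderately |severely )?(?:enlarged|dilated)	regex	target
# --- numeric anchors ---------------------------------------------------------
MAX_LV_WALL_THICKNESS	maximal thickness	literal	target
MAX_LV_WALL_THICKNESS	maximal wall thickness	literal	target
MAX_LV_WALL_THICKNESS	maximum wall thickness	literal	target
MAX_LV_WALL_THICKNESS	maximal LV wall thickness	literal	target
MAX_LV_WALL_THICKNESS	maximal left ventricular wall thickness	literal	target
MAX_LV_WALL_THICKNESS	maximal septal thickness	literal	target
LV_MASS	LV end diastolic mass	literal	target
LV_MASS	LV end[- ]diastolic mass	regex	target
LV_MASS	LV mass	literal	target
LV_MASS	left ventricular mass	literal	target
LV_MASS_INDEX	LV end diastolic mass index	literal	target
LV_MASS_INDEX	LV end[- ]diastolic mass index	regex	target
LV_MASS_INDEX	LV mass index	literal	target
LV_MASS_INDEX	left ventricular mass index	literal	target
LV_EF	left ventricular ejection fraction	literal	target
LV_EF	LV ejection fraction	literal	target
LV_EF	LVEF	literal	target
RV_EF	right ventricular ejection fraction	literal	target
RV_EF	RV ejection fraction	literal	target
RV_EF	RVEF	literal	target
# --- negation cues -----------------------------------------------------------
ALL	no	literal	negation_cue
ALL	no evidence of	literal	negation_cue
ALL	no evidence for	literal	negation_cue
ALL	without	literal	negation_cue
ALL	without evidence of	literal	negation_cue
ALL	not	literal	negation_cue
ALL	not present	literal	negation_cue
ALL	not seen	literal	negation_cue
ALL	not identified	literal	negation_cue
ALL	not visualized	literal	negation_cue
ALL	not demonstrated	literal	negation_cue
ALL	not appreciated	literal	negation_cue
ALL	absent	literal	negation_cue
ALL	is absent	literal	negation_cue
ALL	are absent	literal	negation_cue
ALL	negative for	literal	negation_cue
ALL	free of	literal	negation_cue
ALL	has resolved	literal	negation_cue
ALL	ruled out	literal	negation_cue
# --- hedge cues --------------------------------------------------------------
ALL	possible	literal	hedge_cue
ALL	possibly	literal	hedge_cue
ALL	probable	literal	hedge_cue
ALL	probably	literal	hedge_cue
ALL	suggestive of	literal	hedge_cue
ALL	suspicious for	literal	hedge_cue
ALL	cannot exclude	literal	hedge_cue
ALL	cannot be excluded	literal	hedge_cue
ALL	may represent	literal	hedge_cue
ALL	borderline	literal	hedge_cue
ALL	equivocal	literal	hedge_cue
ALL	question of	literal	hedge_cue
ALL	questionable	literal	hedge_cue
# --- pseudo-negations --------------------------------------------------------
ALL	no change	literal	pseudo_negation
ALL	no change in	literal	pseudo_negation
ALL	no interval change	literal	pseudo_negation
ALL	no significant change	literal	pseudo_negation
ALL	no increase	literal	pseudo_negation
ALL	not ruled out	literal	pseudo_negation
ALL	cannot be ruled out	literal	pseudo_negation
ALL	not excluded	literal	pseudo_negation
# --- termination tokens ------------------------------------------------------
ALL	but	literal	termination
ALL	however	literal	termination
ALL	although	literal	termination
ALL	though	literal	termination
ALL	except	literal	termination
ALL	aside from	literal	termination
ALL	apart from	literal	termination
ALL	;	regex	termination
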