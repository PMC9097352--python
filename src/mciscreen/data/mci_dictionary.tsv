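#mciscreen-dictionary
#version: table1-reconstruction-1.0
#fields: cui	role	max_gap	description	patterns
S_EXCL	patient_exclusion	2	References to stroke (used to exclude patients from analysis)	stroke|cva|cerebrovascular accident|tia|transient ischemic attack
WITHX	feature	2	Patient accompanied by family member	accompanied by daughter|accompanied by son|accompanied by wife|accompanied by husband|accompanied by family|here with daughter|here with son
RESPONS	feature	2	Responsibility being assumed by family member	daughter manages medications|son manages medications|family manages medications|daughter handles finances|responsible for medications|family assumed responsibility
NEGATE	feature	2	Atenolol, hypercalcemia, statins, and remember-to-take boilerplate language	remember to take|atenolol|statin|simvastatin|atorvastatin|hypercalcemia
HALLUC	feature	2	Hallucination issues	hallucination|hallucinate|hearing voices|seeing things
HEADACHE	feature	2	Headache or concern for stroke or brain injury	headache|migraine|head pain
W_EXCL	patient_exclusion	2	Traumatic brain injury, dehydration, etc. (used to exclude patients from analysis)	traumatic brain injury|tbi|dehydration|concussion|head trauma
DECLINE	feature	2	Declining memory or cognitive abilities	memory decline|declining memory|cognitive decline|loss cognitive ability|memory loss|worsening memory|memory problems
WANDER	feature	2	Wandering, getting lost, or unable to recognize	wander|getting lost|got lost|unable to recognize|lost in familiar places
CALLED	feature	2	Reference to communication going through family member	daughter called|son called|wife called|husband called|family called|call from daughter|call from son
FORGET	feature	2	Forget / can't remember	forget|can't remember|cannot remember|unable to remember
DONEPEZIL	feature	2	Donepezil or Aricept discussed	donepezil|aricept
CONCERN	feature	2	Family showing concern for patient	daughter concerned|son concerned|family concerned|wife concerned|husband concerned|family worried|concerned about memory
FORGETFL	feature	2	Forgetful	forgetful|forgetfulness|increasingly forgetful
EXAM	feature	2	Cognitive evaluation	mmse|moca|mini mental|cognitive exam|cognitive testing|montreal cognitive assessment|cognitive evaluation
OTHER_SA	feature	2	Communication goes through family members	speaks through daughter|speaks through son|communication through family|answers provided by daughter|answers provided by son
S_HALLUC	feature	2	Strong hallucination concern	frequent hallucinations|persistent hallucinations|worsening hallucinations|severe hallucinations
ICD_EXCL	feature	2	Dementia ICD diagnosis code appearing in text	f03|g30|294 10|290 0|dementia code
DEMENTIA	feature	2	Severe dementia noted	severe dementia|advanced dementia|end stage dementia|significant dementia
REFERAL	feature	2	Referral for cognitive assessment	referred for cognitive|referral for memory|memory clinic referral|refer to memory clinic
COMPREHE	feature	2	Poor understanding or comprehension	poor comprehension|difficulty understanding|does not understand|unable to comprehend|poor understanding
W_DECLIN	feature	2	Decline in word finding, vocabulary, explaining	word finding difficulty|trouble finding words|word finding problems|difficulty explaining|vocabulary decline
CONCENTR	feature	2	Difficulty concentrating	difficulty concentrating|poor concentration|trouble concentrating|unable to concentrate|trouble focusing
EARLY	feature	2	Early dementia	early dementia|early cognitive impairment|mild dementia
DECLINE_	feature	2	Communication or call concerning memory decline	called about memory|call concerning memory|called regarding memory|call about cognitive decline
FORGETX	feature	2	Forget something, e.g. keys	forgets keys|forgot keys|forgets appointments|forgot appointments|leaves stove on|misplaces items|loses keys
S_CONCER	feature	2	Worsening or strong concern for dementia	strong concern for dementia|worsening concern|very concerned about dementia|serious concern about memory
PLAN	feature	2	Related care plan to family member	care plan discussed with daughter|care plan discussed with son|plan reviewed with family|discussed plan with family
HAL_EXCL	feature	2	Hallucination issues resolved	hallucinations resolved|hallucination resolved|no further hallucinations
BOI_INCL	feature	2	Boilerplate text describing memory problems not necessarily specific to the patient	memory problems are common|normal age related memory|memory changes with aging
OTH_EXCL	feature	2	Headache or memory complaint relating to non-patient	mother had dementia|father had dementia|family history of dementia|husband has memory problems|wife has memory problems
RISK	feature	2	Risk of dementia	risk of dementia|dementia risk|at risk for dementia|risk for cognitive decline
W_CONCER	feature	2	Concern for word finding, vocabulary, explaining	concern about word finding|worried about word finding|concern about vocabulary
ICD_INCL	feature	2	MCI ICD diagnosis code appearing in text but not in structured data	g31 84|331 83|mci code|mild cognitive impairment code
DENIAL	feature	2	Patient denies problem with memory or functioning	denies memory problems|denies memory loss|no memory complaints|denies confusion|denies cognitive problems
EXM_EXCL	feature	2	Normal cognitive exam	normal cognitive exam|mmse normal|moca normal|cognition intact|normal mental status
STIMULANT	feature	2	Stimulant medications (modafinil, Provigil, etc.)	modafinil|provigil|methylphenidate|ritalin|adderall|dextroamphetamine
SENILE	feature	2	Not thinking well, not lucid	senile|not lucid|not thinking clearly|confused thinking
BURDEN	feature	2	Burden on family member	caregiver burden|burden on daughter|burden on son|burden on family|caregiver stress
BOOK	feature	2	Names of relevant books, including 36-Hour Day, Dignified Life, Ageless Outings	36 hour day|dignified life|ageless outings
EXCLUDE	feature	2	Words referencing forgetfulness excluded because of ambiguity concerns	don't forget|do not forget
WELLNESS	feature	2	Wellness check	
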