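# Synthetic illustrative TdP-risk catalog (CredibleMeds-style categories).
# Example data for testing and demonstration only; not a clinical reference.
drug_name	risk_category	synonyms
haloperidol	KNOWN_RISK	haldol
thioridazine	KNOWN_RISK
ziprasidone	KNOWN_RISK	geodon
citalopram	KNOWN_RISK	celexa
escitalopram	KNOWN_RISK	lexapro
methadone	KNOWN_RISK
ondansetron	KNOWN_RISK	zofran
chlorpromazine	KNOWN_RISK
droperidol	KNOWN_RISK
erythromycin	KNOWN_RISK
clozapine	POSSIBLE_RISK	clozaril
mirtazapine	POSSIBLE_RISK	remeron
risperidone	POSSIBLE_RISK	risperdal
quetiapine	POSSIBLE_RISK	seroquel
lithium	POSSIBLE_RISK
venlafaxine	POSSIBLE_RISK	effexor
olanzapine	CONDITIONAL_RISK	zyprexa
sertraline	CONDITIONAL_RISK	zoloft
fluoxetine	CONDITIONAL_RISK	prozac
amitriptyline	CONDITIONAL_RISK
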