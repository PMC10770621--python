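# Late-stage (phase III/IV) cardiovascular drug-target records for the three
# druggable prioritized heart proteins (ADRA1A, PPARG, ROCK2): 15 drugs,
# 5 mechanisms of action, 13 cardiovascular indications.
# Gene symbols follow HGNC: ADRA1A (alpha-1A adrenergic receptor) is used here,
# not the variant spelling "ADRA1A1" that appears in some secondary sources.
# Drug-to-indication pairing is reconstructed by clinical plausibility from
# public trial registries; drug, target, mechanism and phase are as curated.
drug	target	mechanism	max_phase	indications
carvedilol	ADRA1A	adrenergic receptor antagonist	4	heart failure;dilated cardiomyopathy;atrial fibrillation;cardiac arrhythmia
labetalol	ADRA1A	adrenergic receptor antagonist	4	hypertension;preeclampsia
doxazosin	ADRA1A	adrenergic receptor antagonist	4	hypertension
bunazosin	ADRA1A	adrenergic receptor antagonist	3	hypertension
terazosin	ADRA1A	adrenergic receptor antagonist	4	hypertension
midodrine	ADRA1A	adrenergic receptor agonist	4	hypotension
ephedrine	ADRA1A	adrenergic receptor agonist	4	hypotension
norepinephrine	ADRA1A	adrenergic receptor agonist	4	hypotension;cardiac arrest
phenylephrine	ADRA1A	adrenergic receptor agonist	4	hypotension
epinephrine	ADRA1A	adrenergic receptor agonist	4	cardiac arrest
droxidopa	ADRA1A	norepinephrine precursor	4	hypotension
bezafibrate	PPARG	PPAR receptor agonist	4	atherosclerosis;myocardial infarction;acute coronary syndrome
rosiglitazone	PPARG	PPAR receptor agonist	4	atherosclerosis;coronary artery disease
pioglitazone	PPARG	PPAR receptor agonist	4	atherosclerosis;myocardial ischemia;coronary artery disease
fasudil	ROCK2	Rho-associated kinase inhibitor	3	myocardial ischemia
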