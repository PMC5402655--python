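aspirin	1
ibuprofen	1
paracetamol	1
acetaminophen	1
warfarin	1
heparin	1
insulin	1
metformin	1
amoxicillin	1
atorvastatin	1
simvastatin	1
lisinopril	1
omeprazole	1
ranitidine	1
morphine	2
codeine	1
caffeine	1
nicotine	1
digoxin	1
naproxen	1
diazepam	1
lorazepam	1
sertraline	1
fluoxetine	1
hepatitis	1
vaccine	1
antibody	1
antigen	1
molecule	1
protein	1
enzyme	1
ontology	1
therapy	1
excipient	1
pharmacist	1
bacterium	1
penicillin	1
placebo	2
tablet	3
capsule	4
dose	4
drug	4
pain	4
agent	7
compound	4
solution	5
injection	4
patch	7
cream	4
powder	5
syrup	2
trial	6
reaction	7
interaction	2
effect	6
label	5
class	9
property	5
virus	2
infection	4
treatment	4
prescription	5
pharmacy	2
chemical	2
receptor	3
substance	8
ingredient	3
formulation	3
mixture	5
dosage	2
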