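pt	soc
diarrhoea	Gastrointestinal disorders
nausea	Gastrointestinal disorders
vomiting	Gastrointestinal disorders
stomatitis	Gastrointestinal disorders
constipation	Gastrointestinal disorders
dyspepsia	Gastrointestinal disorders
flatulence	Gastrointestinal disorders
oral pain	Gastrointestinal disorders
retching	Gastrointestinal disorders
palmar-plantar erythrodysaesthesia syndrome	Skin and subcutaneous tissue disorders
rash	Skin and subcutaneous tissue disorders
skin exfoliation	Skin and subcutaneous tissue disorders
skin discoloration	Skin and subcutaneous tissue disorders
pruritus	Skin and subcutaneous tissue disorders
blister	Skin and subcutaneous tissue disorders
nail disorder	Skin and subcutaneous tissue disorders
ingrowing nail	Skin and subcutaneous tissue disorders
dehydration	Metabolism and nutrition disorders
hypokalaemia	Metabolism and nutrition disorders
decreased appetite	Metabolism and nutrition disorders
electrolyte imbalance	Metabolism and nutrition disorders
hepatotoxicity	Hepatobiliary disorders
hyperbilirubinaemia	Hepatobiliary disorders
hepatic cytolysis	Hepatobiliary disorders
blood bilirubin increased	Investigations
hepatic enzyme increased	Investigations
aspartate aminotransferase increased	Investigations
ejection fraction decreased	Investigations
platelet count abnormal	Investigations
blood potassium decreased	Investigations
neuropathy peripheral	Nervous system disorders
memory impairment	Nervous system disorders
headache	Nervous system disorders
dizziness	Nervous system disorders
taste disorder	Nervous system disorders
brain edema	Nervous system disorders
fatigue	General disorders and administration site conditions
pyrexia	General disorders and administration site conditions
oedema peripheral	General disorders and administration site conditions
drug ineffective	General disorders and administration site conditions
disease progression	General disorders and administration site conditions
arthralgia	Musculoskeletal and connective tissue disorders
myalgia	Musculoskeletal and connective tissue disorders
cough	Respiratory, thoracic and mediastinal disorders
dyspnoea	Respiratory, thoracic and mediastinal disorders
epistaxis	Respiratory, thoracic and mediastinal disorders
anaemia	Blood and lymphatic system disorders
thrombocytopenia	Blood and lymphatic system disorders
insomnia	Psychiatric disorders
emotional disorder	Psychiatric disorders
aortic valve incompetence	Cardiac disorders
paronychia	Infections and infestations
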