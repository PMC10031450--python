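# Illustrative symptom lexicon subset (SNOMED-CT-style ids), synthetic curation:
# common pediatric symptoms plus mood/emotional-state terms, which are
# deliberately kept in scope as symptoms.
# term	canonical	concept_id
fever	Fever	SCT:386661006
runny nose	Rhinorrhea	SCT:64531003
cough	Cough	SCT:49727002
congestion	Nasal congestion	SCT:68235000
sore throat	Sore throat	SCT:162397003
headache	Headache	SCT:25064002
migraine	Migraine	SCT:37796009
nausea	Nausea	SCT:422587007
vomiting	Vomiting	SCT:422400008
diarrhea	Diarrhea	SCT:62315008
constipation	Constipation	SCT:14760008
rash	Rash	SCT:271807003
hives	Urticaria	SCT:126485001
itching	Pruritus	SCT:418290006
swelling	Swelling	SCT:65124004
seizure	Seizure	SCT:91175000
seizures	Seizure	SCT:91175000
tremor	Tremor	SCT:26079004
spasm	Muscle spasm	SCT:45352006
spasticity	Spasticity	SCT:221360009
pain	Pain	SCT:22253000
stomach ache	Abdominal pain	SCT:21522001
stomachache	Abdominal pain	SCT:21522001
earache	Ear pain	SCT:16001004
ear infection	Otitis media	SCT:65363002
wheezing	Wheezing	SCT:56018004
shortness of breath	Dyspnea	SCT:267036007
difficulty breathing	Dyspnea	SCT:267036007
fatigue	Fatigue	SCT:84229001
tiredness	Fatigue	SCT:84229001
drowsiness	Drowsiness	SCT:271782001
insomnia	Insomnia	SCT:193462001
trouble sleeping	Insomnia	SCT:193462001
loss of appetite	Decreased appetite	SCT:79890006
poor appetite	Decreased appetite	SCT:79890006
dehydration	Dehydration	SCT:34095006
dizziness	Dizziness	SCT:404640003
drooling	Drooling	SCT:62718007
reflux	Gastroesophageal reflux	SCT:722884003
gagging	Gagging	SCT:15387003
choking	Choking	SCT:70407001
irritability	Irritability	SCT:55929007
fussiness	Irritability	SCT:55929007
anxiety	Anxiety	SCT:48694002
stress	Stress	SCT:73595000
happiness	Happiness	SCT:112080002
sadness	Sadness	SCT:307077003
mood swings	Mood swings	SCT:18963009
agitation	Agitation	SCT:24199005
restlessness	Restlessness	SCT:162221009
aggression	Aggressive behavior	SCT:61372001
bruising	Bruising	SCT:125667009
bleeding	Bleeding	SCT:131148009
nosebleed	Epistaxis	SCT:249366005
sneezing	Sneezing	SCT:76067001
watery eyes	Epiphora	SCT:193982009
red eyes	Red eye	SCT:75705005
pink eye	Conjunctivitis	SCT:9826008
swollen glands	Lymphadenopathy	SCT:30746006
chills	Chills	SCT:43724002
sweating	Sweating	SCT:415690000
night sweats	Night sweats	SCT:42984000
weight loss	Weight loss	SCT:89362005
weakness	Weakness	SCT:13791008
numbness	Numbness	SCT:44077006
tingling	Tingling	SCT:62507009
blurred vision	Blurred vision	SCT:246636008
jaundice	Jaundice	SCT:18165001
pale skin	Pallor	SCT:274643008
dry skin	Dry skin	SCT:16386004
colic	Colic	SCT:9989001
cramps	Muscle cramp	SCT:55300003
low oxygen	Hypoxemia	SCT:389087006
low energy	Fatigue	SCT:84229001
back pain	Back pain	SCT:161891005
chest pain	Chest pain	SCT:29857009
joint pain	Arthralgia	SCT:57676002
muscle aches	Myalgia	SCT:68962001
itchy eyes	Eye pruritus	SCT:401284007
hoarseness	Hoarseness	SCT:50219008
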