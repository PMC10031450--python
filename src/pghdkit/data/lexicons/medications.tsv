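# Illustrative medication lexicon subset (RxNorm-style ids), synthetic curation:
# brand and generic names common in pediatric/chronic home care.
# term	canonical	concept_id
benadryl	Diphenhydramine	RX:203457
diphenhydramine	Diphenhydramine	RX:3498
tylenol	Acetaminophen	RX:202433
acetaminophen	Acetaminophen	RX:161
motrin	Ibuprofen	RX:202488
advil	Ibuprofen	RX:153010
ibuprofen	Ibuprofen	RX:5640
zyrtec	Cetirizine	RX:58930
cetirizine	Cetirizine	RX:20610
claritin	Loratadine	RX:203384
loratadine	Loratadine	RX:28889
singulair	Montelukast	RX:219078
montelukast	Montelukast	RX:88249
albuterol	Albuterol	RX:435
ventolin	Albuterol	RX:202936
proventil	Albuterol	RX:202935
flovent	Fluticasone	RX:217022
fluticasone	Fluticasone	RX:41126
keppra	Levetiracetam	RX:261547
levetiracetam	Levetiracetam	RX:114477
depakote	Valproate	RX:202856
valproate	Valproate	RX:40254
valproic acid	Valproate	RX:11118
topamax	Topiramate	RX:220821
topiramate	Topiramate	RX:38404
baclofen	Baclofen	RX:1292
valium	Diazepam	RX:202763
diazepam	Diazepam	RX:3322
ativan	Lorazepam	RX:202479
lorazepam	Lorazepam	RX:6470
clonidine	Clonidine	RX:2599
melatonin	Melatonin	RX:6916
miralax	Polyethylene Glycol 3350	RX:218340
polyethylene glycol	Polyethylene Glycol 3350	RX:8516
zantac	Ranitidine	RX:202976
ranitidine	Ranitidine	RX:9143
prilosec	Omeprazole	RX:203345
omeprazole	Omeprazole	RX:7646
prevacid	Lansoprazole	RX:217376
lansoprazole	Lansoprazole	RX:17128
amoxicillin	Amoxicillin	RX:723
augmentin	Amoxicillin / Clavulanate	RX:151392
azithromycin	Azithromycin	RX:18631
zithromax	Azithromycin	RX:205532
cephalexin	Cephalexin	RX:2231
keflex	Cephalexin	RX:203167
prednisone	Prednisone	RX:8640
prednisolone	Prednisolone	RX:8638
dexamethasone	Dexamethasone	RX:3264
insulin	Insulin	RX:5856
lantus	Insulin Glargine	RX:285018
humalog	Insulin Lispro	RX:217061
metformin	Metformin	RX:6809
risperdal	Risperidone	RX:217897
risperidone	Risperidone	RX:35636
abilify	Aripiprazole	RX:352393
aripiprazole	Aripiprazole	RX:89013
ritalin	Methylphenidate	RX:202966
concerta	Methylphenidate	RX:284635
methylphenidate	Methylphenidate	RX:6901
adderall	Amphetamine / Dextroamphetamine	RX:213469
guanfacine	Guanfacine	RX:40114
intuniv	Guanfacine	RX:866040
zoloft	Sertraline	RX:82728
sertraline	Sertraline	RX:36437
prozac	Fluoxetine	RX:202363
fluoxetine	Fluoxetine	RX:4493
lexapro	Escitalopram	RX:352741
escitalopram	Escitalopram	RX:321988
trileptal	Oxcarbazepine	RX:258337
oxcarbazepine	Oxcarbazepine	RX:32624
lamictal	Lamotrigine	RX:202740
lamotrigine	Lamotrigine	RX:28439
phenobarbital	Phenobarbital	RX:8134
onfi	Clobazam	RX:1111050
clobazam	Clobazam	RX:21241
epidiolex	Cannabidiol	RX:2045370
cannabidiol	Cannabidiol	RX:1000893
atarax	Hydroxyzine	RX:203143
hydroxyzine	Hydroxyzine	RX:5553
zofran	Ondansetron	RX:196502
ondansetron	Ondansetron	RX:26225
robinul	Glycopyrrolate	RX:204418
glycopyrrolate	Glycopyrrolate	RX:4955
pepcid	Famotidine	RX:202833
famotidine	Famotidine	RX:4278
erythromycin	Erythromycin	RX:4053
nystatin	Nystatin	RX:7597
bactroban	Mupirocin	RX:151136
mupirocin	Mupirocin	RX:42372
hydrocortisone	Hydrocortisone	RX:5492
pulmicort	Budesonide	RX:203212
budesonide	Budesonide	RX:19831
atrovent	Ipratropium	RX:202601
ipratropium	Ipratropium	RX:7213
pulmozyme	Dornase Alfa	RX:215556
dornase alfa	Dornase Alfa	RX:63639
tamiflu	Oseltamivir	RX:260101
oseltamivir	Oseltamivir	RX:136411
zovirax	Acyclovir	RX:202954
acyclovir	Acyclovir	RX:281
gabapentin	Gabapentin	RX:25480
neurontin	Gabapentin	RX:196498
synthroid	Levothyroxine	RX:224920
levothyroxine	Levothyroxine	RX:10582
lasix	Furosemide	RX:202991
furosemide	Furosemide	RX:4603
spironolactone	Spironolactone	RX:9997
enalapril	Enalapril	RX:3827
propranolol	Propranolol	RX:8787
digoxin	Digoxin	RX:3407
sildenafil	Sildenafil	RX:136411
coumadin	Warfarin	RX:202421
warfarin	Warfarin	RX:11289
aspirin	Aspirin	RX:1191
ferrous sulfate	Ferrous Sulfate	RX:310325
folic acid	Folic Acid	RX:4511
vitamin d	Cholecalciferol	RX:2418
morphine	Morphine	RX:7052
oxycodone	Oxycodone	RX:7804
water	Water	RX:11295
water irrigation solution	Sterile Water Irrigation Solution	RX:1164936
saline	Sodium Chloride	RX:9863
sodium chloride	Sodium Chloride	RX:9863
yasmin	Drospirenone / Ethinyl Estradiol	RX:353096
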