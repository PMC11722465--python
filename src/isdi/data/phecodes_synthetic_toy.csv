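phecode,label,category,member_codes,exclusion_lo,exclusion_hi,sex_restriction
295.10,Schizophrenia,Mental disorders,SYN-295.1,295,299.99,
295.00,Schizophrenia and other psychotic disorders,Mental disorders,SYN-295.0,295,299.99,
296.20,Depression,Mental disorders,SYN-296.2,295,299.99,
316.00,Substance addiction and disorders,Mental disorders,SYN-316.0,316,317.99,
317.00,Alcoholism,Mental disorders,SYN-317.0,316,317.99,
250.20,Type 2 diabetes,Endocrine / Metabolic,SYN-250.2,249,250.99,
272.10,Hyperlipidemia,Endocrine / Metabolic,SYN-272.1,272,272.99,
401.10,Essential hypertension,Circulatory,SYN-401.1,401,405.99,
411.40,Coronary atherosclerosis,Circulatory,SYN-411.4,410,414.99,
428.20,Heart failure,Circulatory,SYN-428.2,428,428.99,
172.10,Melanomas of skin,Neoplasms,SYN-172.1,172,172.99,
216.00,"Nevus, non-neoplastic",Neoplasms,SYN-216.0,216,216.99,
174.10,Breast cancer [female],Neoplasms,SYN-174.1,174,175.99,female
218.10,Uterine leiomyoma,Genitourinary,SYN-218.1,218,218.99,female
609.00,"Infertility, male",Genitourinary,SYN-609.0,609,609.99,male
585.30,Chronic kidney disease,Genitourinary,SYN-585.3,585,585.99,
070.30,Viral hepatitis C,Infectious diseases,SYN-070.3,70,70.99,
071.00,Human immunodeficiency virus [HIV] disease,Infectious diseases,SYN-071.0,71,71.99,
496.00,Chronic obstructive pulmonary disease,Respiratory,SYN-496.0,495,496.99,
495.00,Asthma,Respiratory,SYN-495.0,495,496.99,
530.10,Esophagitis and GERD,Digestive,SYN-530.1,530,530.99,
523.00,Gingival and periodontal diseases,Digestive,SYN-523.0,523,523.99,
340.00,Migraine,Neurological,SYN-340.0,340,340.99,
327.30,Sleep apnea,Neurological,SYN-327.3,327,327.99,
696.40,Psoriasis,Dermatologic,SYN-696.4,696,696.99,
702.10,Actinic keratosis,Dermatologic,SYN-702.1,702,702.99,
715.20,Osteoarthrosis,Musculoskeletal,SYN-715.2,715,715.99,
365.10,Glaucoma,Sense Organs,SYN-365.1,365,365.99,
285.00,Anemia,Hematopoietic,SYN-285.0,285,285.99,
801.00,Fracture of skull,Injuries and poisonings,SYN-801.0,800,804.99,
642.10,Preeclampsia,Pregnancy complications,SYN-642.1,642,642.99,female
759.00,Congenital anomalies,Congenital anomalies,SYN-759.0,759,759.99,
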