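item,category,component,unit_cost
imaging_pathology,investigation,investigations,120.0
gp_visit,professional_visit,primary_care,82.0
care_plan_fee,professional_visit,primary_care,150.0
specialist_visit,professional_visit,clinical_specialist,170.0
rheum_nurse_visit,professional_visit,rheumatology_nurse,110.0
allied_health_visit,professional_visit,allied_health,95.0
hosp_bone_fracture,hospitalization,bone_fracture,6000.0
hosp_infection,hospitalization,infection_virus,7500.0
hosp_injection_infusion,hospitalization,injections_infusions,1800.0
hosp_mental_health,hospitalization,mental_health,9000.0
hosp_pain_inflammation,hospitalization,pain_inflammation_investigative,5500.0
hosp_surgery,hospitalization,surgery,14000.0
methotrexate_oral_pack,medication,csDMARDS,25.0
methotrexate_sc_pack,medication,csDMARDS,95.0
hydroxychloroquine_pack,medication,csDMARDS,22.0
sulfasalazine_pack,medication,csDMARDS,30.0
leflunomide_pack,medication,csDMARDS,35.0
adalimumab_pack,medication,bDMARDS,900.0
etanercept_pack,medication,bDMARDS,850.0
infliximab_pack,medication,bDMARDS,750.0
tocilizumab_pack,medication,bDMARDS,880.0
abatacept_pack,medication,bDMARDS,1000.0
secukinumab_pack,medication,bDMARDS,950.0
tofacitinib_pack,medication,tsDMARDS,1150.0
upadacitinib_pack,medication,tsDMARDS,1200.0
baricitinib_pack,medication,tsDMARDS,1150.0
prednisone_pack,medication,oral_corticosteroid,15.0
safety_net_threshold,parameter,safety_net,2250.0
safety_net_rebate_fraction,parameter,safety_net,0.15
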