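id,name,who_recommended,nvipst_suggested,status,preselected,notes
bcg,BCG,true,false,already_introduced,false,
polio,Polio,true,false,already_introduced,false,
dtp_booster,DTP-containing vaccine (booster),true,true,already_introduced,false,
hepb,Hepatitis B,true,true,already_introduced,false,
hib,Haemophilus influenzae type b,true,true,already_introduced,false,
measles,Measles,true,true,already_introduced,false,Given as part of MMR; suggested as measles-rubella
rubella,Rubella,true,true,already_introduced,false,Given as part of MMR; suggested as measles-rubella
mumps,Mumps,true,false,already_introduced,false,Given as part of MMR
rotavirus,Rotavirus,true,true,already_introduced,false,
hpv,Human papillomavirus (HPV),true,true,candidate_preselected,true,
malaria,Malaria,true,true,evaluated,false,
cholera,Cholera,true,true,evaluated,false,
typhoid,Typhoid,true,true,evaluated,false,
dengue,Dengue,true,true,evaluated,false,
shigella,Shigella,false,true,evaluated,false,
hexavalent,Hexavalent (DTaP-IPV-Hib-HepB),false,true,excluded_after_approval,true,Approved before the exercise; voted on but excluded during national rollout
meningitis_multi,Meningitis (multivalent),false,true,evaluated,false,
gonorrhoea,Gonorrhoea,false,true,evaluated,false,
rsv,Respiratory syncytial virus (RSV),false,true,candidate_preselected,true,
ebola,Ebola,false,true,evaluated,false,
chikungunya,Chikungunya,false,true,evaluated,false,
mpox,Mpox,false,true,evaluated,false,
gbs,Group B streptococcus,false,true,evaluated,false,
tb_new,Tuberculosis (new vaccine),false,true,evaluated,false,
hepe,Hepatitis E,false,true,evaluated,false,
hepa,Hepatitis A,true,false,evaluated,false,
pcv_hr,Pneumococcal conjugate (high-risk groups),true,false,candidate_preselected,true,
men_b,Meningococcal group B,true,false,evaluated,false,
flu_hr,Seasonal influenza (high-risk groups),true,false,candidate_preselected,true,
varicella,Chickenpox (varicella),true,false,candidate_preselected,true,
tdap,Acellular pertussis (Tdap),false,false,candidate_preselected,true,
zoster,Zoster (shingles),false,false,evaluated,false,
rabies,Rabies,true,false,not_considered,false,
je,Japanese encephalitis,true,false,not_considered,false,Recommended only in endemic areas
yellow_fever,Yellow fever,true,false,not_considered,false,Recommended only in endemic areas
tbe,Tick-borne encephalitis,true,false,not_considered,false,Recommended only in endemic areas
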