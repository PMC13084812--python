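id,name,vote_pct,rank_position,category,dimension,inclusion_status,indicators
effectiveness,"Vaccine effectiveness, including in different populations/age groups/cohorts",100,1,essential,importance,included,
mortality,"Mortality and lethality, including in different sociodemographic and age groups",100,2,essential,importance,included,
incidence,"Incidence in different sociodemographic and age groups",100,3,essential,importance,included,
aefi_risk,"Risk at individual level: type, severity, consequences and frequency of AEFI, including reactogenicity and capacity to mitigate known adverse events",90,4,essential,feasibility,included,
dalys,"Disability-adjusted life years",80,5,significant,importance,included,
alternatives,"Absence of satisfactory alternatives to prevent/treat the disease (effectiveness, cost and practicality)",80,6,essential,importance,included,
complications,"Long-term disease complications (e.g. frequency of survivors with sequelae)",80,7,other,importance,included,
market_availability,"Market availability of the vaccine and supplies over the selected time period",80,8,essential,feasibility,included,
funding,"Availability and sustainability of funding to cover the total cost of the programme (incl. GAVI eligibility)",70,9,essential,feasibility,included,
efficacy_immunogenicity,"Efficacy and immunogenicity of the vaccine in the target population",70,10,significant,,merged_into:effectiveness,
prevalence,"Prevalence across different sociodemographic and age groups",70,11,essential,,excluded_overlap,
serotype_coverage,"Coverage of active serogroups or serotypes in the country (for serogroup- or serotype-specific vaccines)",50,12,essential,importance,included,
waning,"Duration of protection and waning of immunity",50,13,essential,importance,included,
who_prequalification,"Prequalified by WHO",50,14,other,,excluded_nondiscriminating,
market_sustainability,"Sustainability of the market availability of the vaccine and supplies in the longer term",50,15,significant,,excluded_overlap,
outbreak_potential,"Outbreak potential incl. past outbreaks, potential for international spread, and epidemic and pandemic risk",40,16,significant,importance,included,
qaly_loss,"Loss of quality-adjusted life years",40,17,other,,excluded_overlap,
socioeconomic_benefits,"Social and economic benefits, incl. reduction in healthcare costs, improvement in life expectancy and quality of life, productivity gains",40,18,other,,excluded_too_complex,
amr_impact,"Impact on resistance to antibiotics and antivirals",40,19,other,importance,included,
transmission_effect,"Effect of the vaccine on transmission",40,20,other,importance,included,
nnv,"Number needed to vaccinate to prevent a case",40,21,other,importance,included,
global_goals,"Contribution to national/regional/global goals (eradication, control, elimination, reduction)",30,22,significant,,excluded_balance,
patient_costs,"Direct and indirect costs to patients and families",30,23,significant,,excluded_balance,
equity_access,"Accessibility and equity of vaccination for the target population",30,24,other,,excluded_nondiscriminating,
cold_chain,"Availability of adequate cold chain equipment at all levels, or ability to procure required CCE",30,25,essential,,excluded_nondiscriminating,
schedule_fit,"Acceptability of schedule (e.g. multiple injections, additional visits)",30,26,essential,feasibility,included,
burden_inequity,"Burden inequity (highest prevalence in poorer/at-risk populations, gender inequity)",30,27,significant,,excluded_balance,
risk_perception,"Perception of the target population of disease risk, severity, fear and demand for disease control",30,28,essential,,excluded_balance,
price_perspective,"Perspective on vaccine price",30,29,other,feasibility,included,
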