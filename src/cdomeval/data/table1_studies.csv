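study_id,name,design,sample_size_text,recruitment_years,age_at_recruitment,uses_self_report,uses_examinations,uses_admin_databases,collects_incident_outcomes,field_exemptions
carla,CARLA (Cardiovascular Disease Living and Ageing in Halle),cohort,"1,779",2002-2006,45-83 y,true,true,true,true,
degs1,DEGS1 (German Health Interview and Examination Survey for Adults),mixed,"8,152",2008-2011,18-79 y,true,true,false,true,
donald,DONALD (Dortmund Nutritional and Anthropometric Longitudinally Designed Study),cohort,"~2,300",since 1985 (ongoing),3 mo,true,true,false,true,
epic_heidelberg,EPIC-Heidelberg (European Prospective Investigation into Cancer and Nutrition - Heidelberg cohort),cohort,"25,540",1994-1998,35-65 y,true,true,true,true,
epic_potsdam,EPIC-Potsdam (European Prospective Investigation into Cancer and Nutrition - Potsdam cohort),cohort,"27,548",1994-1998,35-65 y,true,true,true,true,
geda,GEDA - multiple studies 2009-2021 (German Health Update),repeated_cross_sectional,"19,294-24,016 per survey",2009-2015,18-79+ y,true,false,false,false,icd10_available;sr_verification_validation
ghs,GHS (Gutenberg Health Study),cohort,"15,010",2007-2012,35-74 y,true,true,true,true,
gnhies98,GNHIES98/BGS98 (German National Health Interview and Examination Survey 1998),cross_sectional,"7,124",1997-1999,18-79 y,true,true,false,false,
hchs,HCHS (Hamburg City Health Study),cohort,"~45,000",since 2015 (ongoing),45-74 y,true,true,true,true,
hnrs,HNRS (Heinz Nixdorf Recall Study),cohort,"4,814",2000-2003,45-75 y,true,true,true,true,
idefics_ifamily,IDEFICS/I.Family,cohort,"16,228 (IDEFICS) / 9,617 (I.Family)",2007-2008,2-10 y,true,true,true,true,
kora,KORA (Cooperative Health Research in the Region of Augsburg),cohort,"S1-S4: 4,022-4,940 each",1984-2001,25-74 y,true,true,true,true,
lida,lidA (German Cohort Study on Work Age Health and Work Participation),cohort,"6,585",2011,46 and 52 y,true,false,true,true,
life_adult,LIFE-Adult (Leipzig Research Centre for Civilization Diseases - Adult study),cohort,"10,000",2011-2014,18-80 y,true,true,true,true,
nako,NAKO (German National Cohort),cohort,">205,000",2014-2019,20-69 y,true,true,true,true,
ship,SHIP/SHIP Trend (Study of Health in Pomerania),cohort,"4,308 / 4,420",1997-2001 / 2008-2012,20-79 y,true,true,true,true,
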