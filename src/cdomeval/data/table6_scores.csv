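study_id,source,prevalent_incident,icd10_available,primary_secondary,sr_mode_device,sr_domain,sr_reference_period,sr_verification_validation,study_examinations,administrative_databases
carla,scientific_publications,2,2,3,3,2,2,3,3,3
carla,study_website,1 (3),0 (3),3 (3),0 (3),0 (3),0 (3),0 (3),0 (3),0 (3)
carla,study_trial_registries,0 (2),0 (0),0 (0),0 (0),0 (1),0 (1),0 (0),1 (2),0 (0)
carla,data_documents,3,3,0,3,3,3,3,3,0
degs1,scientific_publications,2,0,3,3,3,3,0,3,na.
degs1,study_website,1 (2),0 (0),3 (3),1 (3),2 (3),1 (3),0 (0),1 (3),na.
degs1,study_trial_registries,na.,na.,na.,na.,na.,na.,na.,na.,na.
degs1,data_documents,2,0,0,0,3,3,0,3,na.
donald,scientific_publications,3,3,3,2,3,3,0,3,na.
donald,study_website,3 (3),0 (3),3 (3),0 (2),2 (3),3 (3),0 (0),2 (2),na.
donald,study_trial_registries,3 (3),0 (3),3 (3),3 (3),0 (2),0 (3),0 (0),2 (2),na.
donald,data_documents,na.,na.,na.,na.,na.,na.,na.,na.,na.
epic_heidelberg,scientific_publications,3,2,3,3,3,2,3,3,3
epic_heidelberg,study_website,2 (3),0 (0),0 (3),0 (3),3 (3),1 (2),1 (3),1 (3),2 (3)
epic_heidelberg,study_trial_registries,na.,na.,na.,na.,na.,na.,na.,na.,na.
epic_heidelberg,data_documents,na.,na.,na.,na.,na.,na.,na.,na.,na.
epic_potsdam,scientific_publications,3,2,3,3,3,2,3,3,3
epic_potsdam,study_website,2 (2),0 (0),0 (3),2 (3),1 (3),1 (1),3 (3),1 (3),1 (3)
epic_potsdam,study_trial_registries,2 (2),2 (2),3 (3),1 (1),3 (3),0 (1),1 (1),1 (3),1 (1)
epic_potsdam,data_documents,na.,na.,na.,na.,na.,na.,na.,na.,na.
geda,scientific_publications,3,na.,3,3,3,3,na.,na.,na.
geda,study_website,1 (3),na.,3 (3),3 (3),0 (3),0 (3),na.,na.,na.
geda,study_trial_registries,na.,na.,na.,na.,na.,na.,na.,na.,na.
geda,data_documents,3,na.,0,0,3,3,na.,na.,na.
ghs,scientific_publications,3,2,3,3,3,3,3,3,3
ghs,study_website,0 (0),0 (0),3 (3),3 (3),1 (1),1 (1),0 (0),2 (2),0 (0)
ghs,study_trial_registries,0 (0),0 (0),3 (3),0 (0),0 (1),0 (1),0 (0),0 (2),0 (0)
ghs,data_documents,na.,na.,na.,na.,na.,na.,na.,na.,na.
gnhies98,scientific_publications,2,0,3,2,2,2,2,2,na.
gnhies98,study_website,0 (2),0 (0),3 (3),2 (2),0 (2),0 (2),0 (0),0 (2),na.
gnhies98,study_trial_registries,na.,na.,na.,na.,na.,na.,na.,na.,na.
gnhies98,data_documents,3,0,0,0,3,3,0,1,na.
hchs,scientific_publications,3,0,3,3,1,0,3,2,3
hchs,study_website,0 (3),0 (0),0 (3),0 (3),0 (1),0 (0),0 (3),0 (2),0 (3)
hchs,study_trial_registries,2 (3),0 (0),3 (3),1 (3),0 (1),0 (0),0 (3),1 (2),0 (3)
hchs,data_documents,na.,na.,na.,na.,na.,na.,na.,na.,na.
hnrs,scientific_publications,3,2,3,3,2,1,3,3,3
hnrs,study_website,0 (0),0 (0),2 (0),0 (0),0 (0),0 (0),0 (0),0 (0),0 (0)
hnrs,study_trial_registries,0 (2),0 (0),3 (3),0 (2),1 (1),0 (1),0 (1),1 (2),1 (1)
hnrs,data_documents,na.,na.,na.,na.,na.,na.,na.,na.,na.
idefics_ifamily,scientific_publications,3,3,3,3,3,3,2,3,3
idefics_ifamily,study_website,1 (3),0 (3),0 (3),0 (3),0 (3),0 (0),0 (2),1 (3),0 (3)
idefics_ifamily,study_trial_registries,2 (3),0 (3),3 (3),0 (3),0 (3),0 (3),0 (2),1 (3),1 (3)
idefics_ifamily,data_documents,3,0,0,3,3,3,0,3,0
kora,scientific_publications,3,2,3,3,2,2,2,3,3
kora,study_website,1 (2),0 (2),3 (3),1 (3),0 (2),0 (2),0 (2),1 (2),0 (3)
kora,study_trial_registries,3 (3),3 (3),2 (3),1 (3),3 (3),2 (2),3 (3),1 (2),1 (3)
kora,data_documents,3,1,0,1,3,3,2,2,0
lida,scientific_publications,0,3,3,3,0,0,3,na.,3
lida,study_website,0 (0),0 (3),0 (3),1 (3),0 (0),0 (0),0 (3),na.,3 (3)
lida,study_trial_registries,na.,na.,na.,na.,na.,na.,na.,na.,na.
lida,data_documents,3,0,0,3,3,3,0,na.,0
life_adult,scientific_publications,2,0,3,3,3,3,3,3,3
life_adult,study_website,0 (2),0 (0),2 (3),1 (2),0 (2),0 (1),0 (2),1 (2),0 (0)
life_adult,study_trial_registries,0 (2),0 (0),3 (3),0 (2),0 (2),0 (1),0 (2),0 (2),0 (0)
life_adult,data_documents,3,0,0,1,3,3,0,3,0
nako,scientific_publications,3,3,3,3,3,3,3,3,3
nako,study_website,0 (3),0 (3),3 (3),1 (3),0 (3),0 (3),3 (3),1 (3),0 (3)
nako,study_trial_registries,2 (3),0 (3),3 (3),0 (3),0 (3),0 (3),0 (3),1 (3),2 (3)
nako,data_documents,3,2,0,1,3,3,0,3,0
ship,scientific_publications,3,3,3,3,3,1,3,3,3
ship,study_website,3 (3),0 (0),3 (3),0 (2),0 (2),0 (2),0 (3),0 (3),0 (0)
ship,study_trial_registries,3 (3),2 (2),3 (3),2 (3),3 (3),3 (3),2 (3),1 (3),3 (3)
ship,data_documents,3,2,0,2,3,3,0,1,0
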