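study_id,infrastructure_available,accessibility,overall_status
carla,true,open_no_registration,complete_all
degs1,true,open_no_registration,partial
donald,false,not_applicable,partial
epic_heidelberg,false,not_applicable,complete_some
epic_potsdam,false,not_applicable,complete_some
geda,true,open_no_registration,complete_all
ghs,false,not_applicable,complete_some
gnhies98,true,open_no_registration,partial
hchs,true,no_registration_option,partial
hnrs,false,not_applicable,partial
idefics_ifamily,true,registration_required,complete_some
kora,true,registration_required,complete_all
lida,true,open_no_registration,complete_all
life_adult,true,registration_required,partial
nako,true,open_no_registration,complete_all
ship,true,open_no_registration,complete_all
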