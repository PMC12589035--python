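section,category,count
total,irae_reports,147854
total,iae_cases,18068
sex,Female,6167
sex,Male,10812
sex,Missing,1089
age,<18,31
age,18-45,911
age,45-65,5216
age,>=65,8803
reporter,Physician,8254
reporter,Consumer,3920
reporter,Pharmacist,3108
reporter,Other health-professional,2605
report_type,Serious,17498
report_type,Non-serious,570
drug_class,anti-PD-1,12153
drug_class,anti-PD-L1,3945
drug_class,anti-CTLA-4,1970
drug_class,combination,1929
pathogen,Infections - pathogen unspecified,15593
pathogen,Viral infectious disorders,2659
pathogen,Bacterial infectious disorders,2543
pathogen,Fungal infectious disorders,997
outcome,Hospitalization,12135
outcome,Death,4906
outcome,Life-Threatening,2091
outcome,Other Serious,13599
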