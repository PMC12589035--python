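pt,hlt,hlgt,soc
Pneumonia,Lower respiratory tract infections,Infections - pathogen unspecified,Infections and infestations
Pneumonia aspiration,Lower respiratory tract infections,Infections - pathogen unspecified,Infections and infestations
Lower respiratory tract infection,Lower respiratory tract infections,Infections - pathogen unspecified,Infections and infestations
Bronchitis,Lower respiratory tract infections,Infections - pathogen unspecified,Infections and infestations
Sepsis,Sepsis bacteraemia viraemia and fungaemia NEC,Infections - pathogen unspecified,Infections and infestations
Septic shock,Sepsis bacteraemia viraemia and fungaemia NEC,Infections - pathogen unspecified,Infections and infestations
Urinary tract infection,Urinary tract infections,Infections - pathogen unspecified,Infections and infestations
Encephalitis,Central nervous system infections,Infections - pathogen unspecified,Infections and infestations
Meningitis,Central nervous system infections,Infections - pathogen unspecified,Infections and infestations
Meningitis aseptic,Central nervous system infections,Infections - pathogen unspecified,Infections and infestations
Nasopharyngitis,Upper respiratory tract infections,Infections - pathogen unspecified,Infections and infestations
COVID-19,Coronavirus infections,Viral infectious disorders,Infections and infestations
COVID-19 pneumonia,Coronavirus infections,Viral infectious disorders,Infections and infestations
Coronavirus infection,Coronavirus infections,Viral infectious disorders,Infections and infestations
Herpes zoster,Herpes viral infections,Viral infectious disorders,Infections and infestations
Cytomegalovirus infection,Herpes viral infections,Viral infectious disorders,Infections and infestations
Cytomegalovirus enterocolitis,Herpes viral infections,Viral infectious disorders,Infections and infestations
Influenza,Influenza viral infections,Viral infectious disorders,Infections and infestations
Viral infection,Viral infections NEC,Viral infectious disorders,Infections and infestations
Pneumonia bacterial,Bacterial lower respiratory tract infections,Bacterial infectious disorders,Infections and infestations
Cellulitis,Skin and soft tissue bacterial infections,Bacterial infectious disorders,Infections and infestations
Erysipelas,Streptococcal infections,Bacterial infectious disorders,Infections and infestations
Clostridium difficile colitis,Clostridia infections,Bacterial infectious disorders,Infections and infestations
Clostridium difficile infection,Clostridia infections,Bacterial infectious disorders,Infections and infestations
Staphylococcal infection,Staphylococcal infections,Bacterial infectious disorders,Infections and infestations
Bacterial infection,Bacterial infections NEC,Bacterial infectious disorders,Infections and infestations
Relapsing fever,Borrelia infections,Bacterial infectious disorders,Infections and infestations
Pneumocystis jirovecii pneumonia,Pneumocystis infections,Fungal infectious disorders,Infections and infestations
Oral candidiasis,Candida infections,Fungal infectious disorders,Infections and infestations
Candida infection,Candida infections,Fungal infectious disorders,Infections and infestations
Bronchopulmonary aspergillosis,Aspergillus infections,Fungal infectious disorders,Infections and infestations
Aspergillus infection,Aspergillus infections,Fungal infectious disorders,Infections and infestations
Fungal infection,Fungal infections NEC,Fungal infectious disorders,Infections and infestations
Tuberculosis,Tuberculous infections,Mycobacterial infectious disorders,Infections and infestations
Pulmonary tuberculosis,Tuberculous infections,Mycobacterial infectious disorders,Infections and infestations
Latent tuberculosis,Tuberculous infections,Mycobacterial infectious disorders,Infections and infestations
Atypical mycobacterial infection,Atypical mycobacterial infections,Mycobacterial infectious disorders,Infections and infestations
Acarodermatitis,Mite and tick infestations,Ectoparasitic disorders,Infections and infestations
Myiasis,Fly infestations,Ectoparasitic disorders,Infections and infestations
Amoebic colitis,Amoebic infections,Protozoal infectious disorders,Infections and infestations
Infection protozoal,Protozoal infections NEC,Protozoal infectious disorders,Infections and infestations
Rash,Rashes eruptions and exanthems NEC,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
Pruritus,Pruritus NEC,Epidermal and dermal conditions,Skin and subcutaneous tissue disorders
Diarrhoea,Diarrhoea (excl infective),Gastrointestinal motility and defaecation conditions,Gastrointestinal disorders
Colitis,Colitis (excl infective),Gastrointestinal inflammatory conditions,Gastrointestinal disorders
Pneumonitis,Lower respiratory tract inflammatory and immunologic conditions,Lower respiratory tract disorders (excl obstruction and infection),Respiratory thoracic and mediastinal disorders
Fatigue,Asthenic conditions,General system disorders NEC,General disorders and administration site conditions
Pyrexia,Febrile disorders,Body temperature conditions,General disorders and administration site conditions
Hepatitis,Hepatic and hepatobiliary disorders NEC,Hepatic and hepatobiliary disorders,Hepatobiliary disorders
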