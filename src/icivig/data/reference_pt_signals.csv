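hlgt,pt,meddra_code,cases,ror,ror_low,ror_high,ic,ic_low,ic_high,flagged
Infections - pathogen unspecified,Pneumonia,10035664,3926,1.81,1.75,1.87,0.84,0.79,0.89,1
Infections - pathogen unspecified,Sepsis,10040047,1737,2.54,2.42,2.66,1.32,1.25,1.39,1
Infections - pathogen unspecified,Urinary tract infection,10046571,1011,0.91,0.86,0.97,-0.13,-0.22,-0.04,0
Infections - pathogen unspecified,Encephalitis,10014581,607,17.25,15.83,18.79,3.91,3.76,4.01,1
Infections - pathogen unspecified,Septic shock,10040070,585,2.29,2.11,2.48,1.18,1.05,1.29,1
Infections - pathogen unspecified,Pneumonia aspiration,10035669,568,3.86,3.55,4.2,1.91,1.78,2.03,1
Infections - pathogen unspecified,Nasopharyngitis,10028810,348,0.28,0.25,0.31,-1.81,-1.96,-1.65,0
Infections - pathogen unspecified,Bronchitis,10006451,256,0.51,0.45,0.57,-0.98,-1.15,-0.79,0
Infections - pathogen unspecified,Meningitis,10027199,241,6.37,5.6,7.26,2.6,2.38,2.77,1
Infections - pathogen unspecified,Meningitis aseptic,10027201,210,8.42,7.32,9.69,2.98,2.73,3.14,1
Infections - pathogen unspecified,Lower respiratory tract infection,10024968,207,0.76,0.66,0.87,-0.4,-0.6,-0.2,0
Viral infectious disorders,COVID-19,10084268,752,0.62,0.58,0.66,-0.69,-0.79,-0.58,0
Viral infectious disorders,Herpes zoster,10019974,344,0.89,0.8,0.99,-0.17,-0.33,-0.01,0
Viral infectious disorders,Influenza,10022000,240,0.34,0.3,0.38,-1.56,-1.74,-1.37,0
Viral infectious disorders,COVID-19 pneumonia,10084380,132,1.58,1.33,1.87,0.65,0.39,0.9,1
Viral infectious disorders,Cytomegalovirus infection,10011831,107,1.05,0.87,1.27,0.07,-0.21,0.34,0
Viral infectious disorders,Viral infection,10047461,85,0.42,0.34,0.52,-1.24,-1.55,-0.92,0
Viral infectious disorders,Coronavirus infection,10051905,70,1.34,1.06,1.69,0.42,0.06,0.75,1
Viral infectious disorders,Cytomegalovirus enterocolitis,10049015,51,12.6,9.44,16.83,3.52,2.83,3.67,1
Bacterial infectious disorders,Pneumonia bacterial,10060946,381,7.49,6.75,8.31,2.82,2.65,2.95,1
Bacterial infectious disorders,Cellulitis,10007882,356,1.08,0.97,1.2,0.11,-0.05,0.26,0
Bacterial infectious disorders,Clostridium difficile colitis,10009657,139,2.11,1.79,2.5,1.07,0.81,1.3,1
Bacterial infectious disorders,Clostridium difficile infection,10054236,137,0.9,0.76,1.07,-0.15,-0.39,0.1,0
Bacterial infectious disorders,Staphylococcal infection,10058080,134,0.68,0.57,0.8,-0.56,-0.81,-0.31,0
Bacterial infectious disorders,Bacterial infection,10060945,83,0.76,0.61,0.94,-0.39,-0.71,-0.07,0
Bacterial infectious disorders,Erysipelas,10015145,74,2.29,1.82,2.88,1.18,0.82,1.49,1
Bacterial infectious disorders,Relapsing fever,10038300,56,37.79,27.92,51.14,4.84,3.83,4.69,1
Fungal infectious disorders,Pneumocystis jirovecii pneumonia,10073755,266,3.78,3.34,4.27,1.88,1.69,2.05,1
Fungal infectious disorders,Oral candidiasis,10030963,121,1.61,1.34,1.92,0.68,0.41,0.93,1
Fungal infectious disorders,Candida infection,10074170,98,0.78,0.64,0.96,-0.35,-0.64,-0.06,0
Fungal infectious disorders,Bronchopulmonary aspergillosis,10006473,85,1.83,1.48,2.27,0.86,0.53,1.16,1
Fungal infectious disorders,Fungal infection,10017533,76,0.34,0.28,0.43,-1.53,-1.85,-1.19,0
Fungal infectious disorders,Aspergillus infection,10074171,50,1.08,0.82,1.43,0.11,-0.29,0.52,0
Mycobacterial infectious disorders,Tuberculosis,10044755,77,0.96,0.77,1.2,-0.06,-0.38,0.27,0
Mycobacterial infectious disorders,Pulmonary tuberculosis,10037440,75,3.1,2.47,3.9,1.61,1.23,1.9,1
Mycobacterial infectious disorders,Atypical mycobacterial infection,10061663,28,3.81,2.62,5.56,1.9,1.22,2.31,1
Mycobacterial infectious disorders,Latent tuberculosis,10065048,10,0.71,0.38,1.32,-0.49,-1.32,0.42,0
Ectoparasitic disorders,Acarodermatitis,10063409,6,0.79,0.35,1.75,-0.35,-1.4,0.79,0
Ectoparasitic disorders,Myiasis,10028586,4,9.8,3.53,27.22,3.18,0.44,3.14,1
Protozoal infectious disorders,Amoebic colitis,10001985,3,5.04,1.59,16.04,2.28,-0.18,2.78,1
Protozoal infectious disorders,Infection protozoal,10021859,1,4.9,0.66,36.28,2.24,-1.41,2.83,0
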