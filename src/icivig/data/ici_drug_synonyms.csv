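canonical,synonym,drug_class
nivolumab,nivolumab,anti-PD-1
nivolumab,OPDIVO,anti-PD-1
nivolumab,NIVOLUMAB BMS,anti-PD-1
pembrolizumab,pembrolizumab,anti-PD-1
pembrolizumab,KEYTRUDA,anti-PD-1
pembrolizumab,lambrolizumab,anti-PD-1
pembrolizumab,MK-3475,anti-PD-1
cemiplimab,cemiplimab,anti-PD-1
cemiplimab,cemiplimab-rwlc,anti-PD-1
cemiplimab,LIBTAYO,anti-PD-1
atezolizumab,atezolizumab,anti-PD-L1
atezolizumab,TECENTRIQ,anti-PD-L1
avelumab,avelumab,anti-PD-L1
avelumab,BAVENCIO,anti-PD-L1
durvalumab,durvalumab,anti-PD-L1
durvalumab,IMFINZI,anti-PD-L1
ipilimumab,ipilimumab,anti-CTLA-4
ipilimumab,YERVOY,anti-CTLA-4
tremelimumab,tremelimumab,anti-CTLA-4
tremelimumab,tremelimumab-actl,anti-CTLA-4
tremelimumab,ticilimumab,anti-CTLA-4
tremelimumab,IMJUDO,anti-CTLA-4
aspirin,aspirin,none
aspirin,acetylsalicylic acid,none
metformin,metformin,none
metformin,metformin hydrochloride,none
metformin,GLUCOPHAGE,none
atorvastatin,atorvastatin,none
atorvastatin,LIPITOR,none
lisinopril,lisinopril,none
methotrexate,methotrexate,none
prednisone,prednisone,none
omeprazole,omeprazole,none
carboplatin,carboplatin,none
pemetrexed,pemetrexed,none
pemetrexed,ALIMTA,none
paclitaxel,paclitaxel,none
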