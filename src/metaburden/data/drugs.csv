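drug_id,antibody,type,molar_mass_kda,dose_mg,cycle_days,half_life_days,note
atezolizumab,Atezolizumab,humanized,145,1200,21,27,1200mg q3w
avelumab,Avelumab,human,143,800,14,6.1,800mg q2w
durvalumab,Durvalumab,human,146,750,14,18,10mg/kg q2w at a 75 kg reference body mass
nivolumab,Nivolumab,human,146,240,14,26.7,240mg q2w
nivolumab-q4w,Nivolumab,human,146,480,28,26.7,480mg q4w
pembrolizumab,Pembrolizumab,humanized,146,200,21,22,200mg q3w
pembrolizumab-q6w,Pembrolizumab,humanized,146,400,42,22,400mg q6w
cemiplimab,Cemiplimab,human,144,350,21,19.4,350mg q3w
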