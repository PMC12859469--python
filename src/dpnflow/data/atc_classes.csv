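atc_prefix,class_label
A,Alimentary and metabolism
B,Blood
C,Cardiovascular
D,Dermatologicals
G,Genitourinary
H,Systemic hormonal
J,Systemic anti-infectives
L,Antineoplastics
M,Musculoskeletal
N01,Anesthetic
N02,Analgesics
N03,Antiepileptics
N04,Antiparkinson
N05A,Antipsychotics
N05B,Anxiolytics
N05C,Hypnotics and sedatives
N06A,Antidepressants
N06B,Psychostimulants
N06D,Antidementia
N07,Other nervous system drugs
N,Other nervous system drugs
P,Antiparasitics
R,Respiratory
S,Sensory
V,Others
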