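acronym,name,parent,is_striatal
BRAIN,whole brain,,0
CTX,cerebral cortex,BRAIN,0
MO,somatomotor areas,CTX,0
MOp,primary motor area,MO,0
MOs,secondary motor area,MO,0
SS,somatosensory areas,CTX,0
SSp,primary somatosensory area,SS,0
SSs,supplemental somatosensory area,SS,0
ORB,orbital area,CTX,0
CLA,claustrum,CTX,0
TH,thalamus,BRAIN,0
VAL,ventral anterior-lateral complex,TH,0
VM,ventral medial nucleus,TH,0
PF,parafascicular nucleus,TH,0
CM,central medial nucleus,TH,0
PAL,pallidum,BRAIN,0
GPe,globus pallidus external segment,PAL,0
STN,subthalamic nucleus,BRAIN,0
MB,midbrain,BRAIN,0
SNc,substantia nigra compact part,MB,0
SNr,substantia nigra reticular part,MB,0
DR,dorsal raphe nucleus,MB,0
BLA,basolateral amygdalar nucleus,BRAIN,0
STR,striatum,BRAIN,1
CP,caudoputamen,STR,1
ACB,nucleus accumbens,STR,1
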