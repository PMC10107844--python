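abbreviation,description
A1,primary auditory cortex
AuD,dorsal auditory cortex
AuV,ventral auditory cortex
MGv,medial geniculate body ventral part
AC_contra,contralateral auditory cortex
MGd,medial geniculate body dorsal part
TeA,temporal association cortex
S1,primary somatosensory cortex
MGm,medial geniculate body medial part
V2,secondary visual cortex
InsC,insular cortex
PPC,posterior parietal cortex
BF,basal forebrain
S2,secondary somatosensory cortex
SG,supra geniculate body
Ect,ectorhinal cortex
V1,primary visual cortex
ZI,zona incerta
TeA_contra,contralateral temporal association cortex
VPL/VPM,ventral posterolateral/posteromedial thalamic nucleus
RSA/RSG,retrosplenial agranular/granular cortex
S1_contra,contralateral primary somatosensory cortex
LP,lateral posterior thalamic nucleus
V2_contra,contralateral secondary visual cortex
ECIC,external cortex of the inferior colliculus
M1,primary motor cortex
MZMG,marginal zone of the medial geniculate
OFC,orbitofrontal cortex
M2,secondary motor cortex
ECIC_2,external cortex of the inferior colliculus (second listing)
LP_contra,contralateral lateral posterior thalamic nucleus
PRh,perirhinal cortex
Ect_contra,contralateral ectorhinal cortex
M1_contra,contralateral primary motor cortex
VA/VL/VM,ventral anterior/lateral/medial thalamic nuclei
AM,anterior medial thalamic nucleus
Po,posterior thalamic nucleus
MEnt,medial entorhinal cortex
InsC_contra,contralateral insular cortex (listed as GI_contra in the proportion block)
B,basal nucleus of Meynert
S,subiculum
HDB,nucleus of the horizontal limb of the diagonal band
LEnt,lateral entorhinal cortex
PRh_contra,contralateral perirhinal cortex
S2_contra,contralateral secondary somatosensory cortex
BMA,basomedial amygdala
PF,parafascicular thalamic nucleus
Raphe,raphe nuclei
Cl,claustrum
CA1,hippocampal CA1
PIL,posterior intralaminar thalamic nucleus
La,lateral amygdala
Others,aggregate of regions with very low counts (kept opaque)
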