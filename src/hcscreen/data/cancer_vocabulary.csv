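# hcscreen cancer vocabulary v1 — synonym,canonical
# canonical set: 36 named tumor types + other_unspecified
bladder,bladder
bladder cancer,bladder
bone,bone
bone cancer,bone
breast,breast
breast cancer,breast
male breast,breast
cervical,cervical
cervix,cervical
cervical cancer,cervical
cns_brain,cns_brain
brain,cns_brain
cns,cns_brain
brain cancer,cns_brain
glioblastoma,cns_brain
colon,colon
colorectal,colon
colon cancer,colon
rectal,colon
rectum,colon
bowel,colon
adrenal,adrenal
adrenal gland,adrenal
esophageal,esophageal
esophagus,esophageal
fallopian_tube,fallopian_tube
fallopian tube,fallopian_tube
gallbladder,gallbladder
bile duct,gallbladder
head_neck,head_neck
head and neck,head_neck
laryngeal,head_neck
oral,head_neck
throat,head_neck
hodgkin_lymphoma,hodgkin_lymphoma
hodgkin's lymphoma,hodgkin_lymphoma
hodgkins lymphoma,hodgkin_lymphoma
hodgkin,hodgkin_lymphoma
keratoacanthoma,keratoacanthoma
leukemia,leukemia
leukaemia,leukemia
aml,leukemia
cll,leukemia
liver,liver
hepatic,liver
hepatocellular,liver
lung,lung
lung cancer,lung
lymphoma_unspecified,lymphoma_unspecified
lymphoma,lymphoma_unspecified
melanoma,melanoma
mesothelioma,mesothelioma
multiple_myeloma,multiple_myeloma
myeloma,multiple_myeloma
non_hodgkin_lymphoma,non_hodgkin_lymphoma
non-hodgkin's lymphoma,non_hodgkin_lymphoma
non-hodgkin lymphoma,non_hodgkin_lymphoma
nhl,non_hodgkin_lymphoma
ovarian,ovarian
ovary,ovarian
ovarian carcinoma,ovarian
pancreatic,pancreatic
pancreas,pancreatic
primary_peritoneal,primary_peritoneal
primary peritoneal,primary_peritoneal
peritoneal,primary_peritoneal
prostate,prostate
prostate cancer,prostate
renal,renal
kidney,renal
renal cell,renal
sarcoma,sarcoma
leiomyosarcoma,sarcoma
liposarcoma,sarcoma
sebaceous,sebaceous
sebaceous adenoma,sebaceous
sebaceous carcinoma,sebaceous
skin_unspecified,skin_unspecified
skin,skin_unspecified
basal cell,skin_unspecified
squamous cell skin,skin_unspecified
small_intestine,small_intestine
small intestinal,small_intestine
small bowel,small_intestine
stomach,stomach
gastric,stomach
testicular,testicular
testis,testicular
thyroid,thyroid
ureter_renal_pelvis,ureter_renal_pelvis
ureter,ureter_renal_pelvis
renal pelvis,ureter_renal_pelvis
urothelial,ureter_renal_pelvis
uterine_endometrial,uterine_endometrial
uterine,uterine_endometrial
uterus,uterine_endometrial
endometrial,uterine_endometrial
endometrium,uterine_endometrial
wilms_tumor,wilms_tumor
wilms' tumor,wilms_tumor
wilms tumor,wilms_tumor
wilms,wilms_tumor
other_unspecified,other_unspecified
other,other_unspecified
unspecified,other_unspecified
unknown,other_unspecified
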