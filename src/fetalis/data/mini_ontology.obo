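format-version: 1.2
ontology: fetalis-mini
remark: Synthetic 40-term miniature phenotype ontology for offline pipeline runs and tests. Term IDs and labels are HPO-style analogs, not real HPO identifiers.

[Term]
id: HP:0000001
name: Phenotypic abnormality

[Term]
id: HP:0000100
name: Abnormality of the skeletal system
is_a: HP:0000001 ! Phenotypic abnormality

[Term]
id: HP:0000110
name: Abnormality of the limbs
is_a: HP:0000100 ! Abnormality of the skeletal system

[Term]
id: HP:0000111
name: Polydactyly
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000112
name: Clinodactyly
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000113
name: Brachydactyly
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000114
name: Talipes equinovarus
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000115
name: Limb reduction defect
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000116
name: Joint contractures
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000117
name: Syndactyly
is_a: HP:0000110 ! Abnormality of the limbs

[Term]
id: HP:0000120
name: Abnormality of the long bones
is_a: HP:0000100 ! Abnormality of the skeletal system

[Term]
id: HP:0000121
name: Short long bones
is_a: HP:0000120 ! Abnormality of the long bones

[Term]
id: HP:0000122
name: Skeletal dysplasia
is_a: HP:0000100 ! Abnormality of the skeletal system

[Term]
id: HP:0000130
name: Short nasal bone
is_a: HP:0000100 ! Abnormality of the skeletal system

[Term]
id: HP:0000140
name: Craniosynostosis
is_a: HP:0000100 ! Abnormality of the skeletal system

[Term]
id: HP:0000200
name: Abnormality of the cardiovascular system
is_a: HP:0000001 ! Phenotypic abnormality

[Term]
id: HP:0000210
name: Congenital heart defect
is_a: HP:0000200 ! Abnormality of the cardiovascular system

[Term]
id: HP:0000211
name: Ventricular septal defect
is_a: HP:0000210 ! Congenital heart defect

[Term]
id: HP:0000220
name: Abnormality of the lymphatic system
is_a: HP:0000200 ! Abnormality of the cardiovascular system

[Term]
id: HP:0000221
name: Cystic hygroma
is_a: HP:0000220 ! Abnormality of the lymphatic system

[Term]
id: HP:0000222
name: Increased nuchal translucency
is_a: HP:0000220 ! Abnormality of the lymphatic system

[Term]
id: HP:0000300
name: Abnormality of the nervous system
is_a: HP:0000001 ! Phenotypic abnormality

[Term]
id: HP:0000310
name: Abnormality of brain morphology
is_a: HP:0000300 ! Abnormality of the nervous system

[Term]
id: HP:0000311
name: Abnormality of the cerebellum
alt_id: HP:0009311
is_a: HP:0000310 ! Abnormality of brain morphology

[Term]
id: HP:0000312
name: Abnormality of the cerebellar vermis
is_a: HP:0000311 ! Abnormality of the cerebellum

[Term]
id: HP:0000313
name: Dandy-Walker malformation
is_a: HP:0000312 ! Abnormality of the cerebellar vermis
is_a: HP:0000310 ! Abnormality of brain morphology

[Term]
id: HP:0000314
name: Hydrocephalus
is_a: HP:0000310 ! Abnormality of brain morphology

[Term]
id: HP:0000315
name: Ventriculomegaly
is_a: HP:0000310 ! Abnormality of brain morphology

[Term]
id: HP:0000316
name: Enlarged cisterna magna
is_a: HP:0000310 ! Abnormality of brain morphology

[Term]
id: HP:0000320
name: Abnormality of the musculature
is_a: HP:0000300 ! Abnormality of the nervous system

[Term]
id: HP:0000321
name: Decreased fetal movement
is_a: HP:0000320 ! Abnormality of the musculature

[Term]
id: HP:0000322
name: Myopathy
is_a: HP:0000320 ! Abnormality of the musculature

[Term]
id: HP:0000400
name: Abnormality of the genitourinary system
is_a: HP:0000001 ! Phenotypic abnormality

[Term]
id: HP:0000410
name: Hydronephrosis
is_a: HP:0000400 ! Abnormality of the genitourinary system

[Term]
id: HP:0000420
name: Hypospadias
is_a: HP:0000400 ! Abnormality of the genitourinary system

[Term]
id: HP:0000430
name: Ambiguous genitalia
is_a: HP:0000400 ! Abnormality of the genitourinary system

[Term]
id: HP:0000500
name: Growth abnormality
is_a: HP:0000001 ! Phenotypic abnormality

[Term]
id: HP:0000510
name: Intrauterine growth retardation
is_a: HP:0000500 ! Growth abnormality

[Term]
id: HP:0000600
name: Abnormality of the digestive system
is_a: HP:0000001 ! Phenotypic abnormality

[Term]
id: HP:0000610
name: Echogenic bowel
is_a: HP:0000600 ! Abnormality of the digestive system

[Term]
id: HP:0000999
name: Retired finding (do not use)
is_obsolete: true
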