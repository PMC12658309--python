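code,system,subgroup,category,match_mode,notes
F70,ICD10,learning disability,neurodevelopmental,prefix,mild intellectual disability
F71,ICD10,learning disability,neurodevelopmental,prefix,moderate intellectual disability
F72,ICD10,learning disability,neurodevelopmental,prefix,severe intellectual disability
F73,ICD10,learning disability,neurodevelopmental,prefix,profound intellectual disability
F78,ICD10,learning disability,neurodevelopmental,prefix,other intellectual disability
F79,ICD10,learning disability,neurodevelopmental,prefix,unspecified intellectual disability
F80,ICD10,developmental disorders,neurodevelopmental,prefix,speech and language development
F81,ICD10,developmental disorders,neurodevelopmental,prefix,scholastic skills
F82,ICD10,developmental disorders,neurodevelopmental,prefix,motor function development
F83,ICD10,developmental disorders,neurodevelopmental,prefix,mixed specific developmental disorders
F84,ICD10,autistic spectrum disorders,neurodevelopmental,prefix,pervasive developmental disorders
F90,ICD10,hyperkinetic disorders,neurodevelopmental,prefix,
F91,ICD10,behavioural (conduct) disorders,neurodevelopmental,prefix,
F95,ICD10,tic disorders,neurodevelopmental,prefix,
G80,ICD10,cerebral palsy,complex neurologic,prefix,
G81,ICD10,cerebral palsy,complex neurologic,prefix,hemiplegia
G82,ICD10,cerebral palsy,complex neurologic,prefix,paraplegia and tetraplegia
G83,ICD10,cerebral palsy,complex neurologic,prefix,other paralytic syndromes
G40,ICD10,epilepsy,complex neurologic,prefix,
G41,ICD10,epilepsy,complex neurologic,prefix,status epilepticus
Q90,ICD10,chromosomal anomalies,inherited/congenital,prefix,Down syndrome
Q91,ICD10,chromosomal anomalies,inherited/congenital,prefix,Edwards and Patau syndromes
Q92,ICD10,chromosomal anomalies,inherited/congenital,prefix,other autosomal trisomies
Q93,ICD10,chromosomal anomalies,inherited/congenital,prefix,monosomies and deletions
Q97,ICD10,sex chromosome anomalies,inherited/congenital,prefix,female phenotype
Q98,ICD10,sex chromosome anomalies,inherited/congenital,prefix,Klinefelter syndrome
Q992,ICD10,sex chromosome anomalies,inherited/congenital,prefix,fragile X
Q00,ICD10,congenital anomalies of cns,inherited/congenital,prefix,anencephaly
Q01,ICD10,congenital anomalies of cns,inherited/congenital,prefix,encephalocele
Q02,ICD10,congenital anomalies of cns,inherited/congenital,prefix,microcephaly
Q03,ICD10,congenital anomalies of cns,inherited/congenital,prefix,congenital hydrocephalus
Q04,ICD10,congenital anomalies of cns,inherited/congenital,prefix,other brain malformations
Q05,ICD10,congenital anomalies of cns,inherited/congenital,prefix,spina bifida
Q06,ICD10,congenital anomalies of cns,inherited/congenital,prefix,spinal cord malformations
Q07,ICD10,congenital anomalies of cns,inherited/congenital,prefix,other nervous system malformations
E030,ICD10,congenital hypothyroidism,inherited/congenital,prefix,with diffuse goitre
E031,ICD10,congenital hypothyroidism,inherited/congenital,prefix,without goitre
Q860,ICD10,foetal alcohol syndrome,inherited/congenital,prefix,
E70,ICD10,inherited metabolic conditions,inherited/congenital,prefix,aromatic amino-acid metabolism
E71,ICD10,inherited metabolic conditions,inherited/congenital,prefix,branched-chain amino-acid metabolism
E72,ICD10,inherited metabolic conditions,inherited/congenital,prefix,other amino-acid metabolism
E75,ICD10,inherited metabolic conditions,inherited/congenital,prefix,sphingolipid metabolism
E76,ICD10,inherited metabolic conditions,inherited/congenital,prefix,glycosaminoglycan metabolism
Q85,ICD10,phakomatoses,inherited/congenital,prefix,neurofibromatosis and tuberous sclerosis
Q87,ICD10,other high-risk congenital anomalies,inherited/congenital,prefix,congenital malformation syndromes
G91,ICD10,hydrocephalus,high-risk brain,prefix,acquired hydrocephalus
A12,OPCS4,hydrocephalus,high-risk brain,prefix,cerebroventricular shunt
I60,ICD10,paediatric stroke,high-risk brain,prefix,subarachnoid haemorrhage
I61,ICD10,paediatric stroke,high-risk brain,prefix,intracerebral haemorrhage
I63,ICD10,paediatric stroke,high-risk brain,prefix,cerebral infarction
I64,ICD10,paediatric stroke,high-risk brain,prefix,stroke unspecified
C70,ICD10,cns tumours,high-risk brain,prefix,meninges
C71,ICD10,cns tumours,high-risk brain,prefix,brain
C72,ICD10,cns tumours,high-risk brain,prefix,spinal cord and cranial nerves
D33,ICD10,cns tumours,high-risk brain,prefix,benign brain and CNS neoplasm
G00,ICD10,inflammatory brain conditions,high-risk brain,prefix,bacterial meningitis
G01,ICD10,inflammatory brain conditions,high-risk brain,prefix,meningitis in bacterial diseases
G02,ICD10,inflammatory brain conditions,high-risk brain,prefix,meningitis in other diseases
G03,ICD10,inflammatory brain conditions,high-risk brain,prefix,other meningitis
G04,ICD10,inflammatory brain conditions,high-risk brain,prefix,encephalitis and myelitis
G05,ICD10,inflammatory brain conditions,high-risk brain,prefix,encephalitis in other diseases
H54,ICD10,bilateral visual impairment,visual impairment,prefix,blindness and low vision
H351,ICD10,high-risk eye conditions,visual impairment,prefix,retinopathy of prematurity
Z962,ICD10,cochlear implant,hearing impairment,prefix,presence of otological implant
D24,OPCS4,cochlear implant,hearing impairment,prefix,operations on cochlea
D13,OPCS4,hearing device,hearing impairment,prefix,bone-anchored hearing device
H90,ICD10,hearing impairment diagnosis,hearing impairment,prefix,conductive and sensorineural loss
H913,ICD10,hearing impairment diagnosis,hearing impairment,exact,deaf mutism
G10,ICD10,degenerative cns disorders,motor function,prefix,Huntington disease
G11,ICD10,degenerative cns disorders,motor function,prefix,hereditary ataxia
G12,ICD10,degenerative cns disorders,motor function,prefix,spinal muscular atrophy
G13,ICD10,degenerative cns disorders,motor function,prefix,systemic atrophies in other diseases
G31,ICD10,degenerative cns disorders,motor function,prefix,other CNS degeneration
G70,ICD10,neuromuscular disorders,motor function,prefix,myasthenia gravis and myoneural
G71,ICD10,neuromuscular disorders,motor function,prefix,primary disorders of muscles
G72,ICD10,neuromuscular disorders,motor function,prefix,other myopathies
G73,ICD10,neuromuscular disorders,motor function,prefix,myoneural disorders in other diseases
G24,ICD10,movement disorders,motor function,prefix,dystonia
G25,ICD10,movement disorders,motor function,prefix,other extrapyramidal disorders
P210,ICD10,severe birth asphyxia,perinatal,prefix,
P52,ICD10,perinatal brain damage,perinatal,prefix,intracranial haemorrhage of newborn
P91,ICD10,perinatal brain damage,perinatal,prefix,cerebral disturbances incl HIE
P961,ICD10,neonatal abstinence syndrome,perinatal,prefix,withdrawal from maternal drug use
P35,ICD10,congenital infections,perinatal,prefix,congenital viral diseases
P070,ICD10,extremely low birth weight,perinatal,prefix,birth weight under 1000 g
P072,ICD10,extreme prematurity,perinatal,prefix,
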