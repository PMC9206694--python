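category,pt
coma_altered_consciousness,Coma
coma_altered_consciousness,Depressed level of consciousness
coma_altered_consciousness,Loss of consciousness
coma_altered_consciousness,Stupor
coma_altered_consciousness,Somnolence
coma_altered_consciousness,Lethargy
coma_altered_consciousness,Encephalopathy
brain_oedema,Brain oedema
brain_oedema,Cerebral oedema
brain_oedema,Intracranial pressure increased
brain_oedema,Brain herniation
seizures,Seizure
seizures,Convulsion
seizures,Status epilepticus
seizures,Generalised tonic-clonic seizure
seizures,Partial seizures
neuropsychiatric,Confusional state
neuropsychiatric,Agitation
neuropsychiatric,Hallucination
neuropsychiatric,Delirium
neuropsychiatric,Psychotic disorder
neuropsychiatric,Disorientation
neuropsychiatric,Aggression
misc_neurological,Tremor
misc_neurological,Ataxia
misc_neurological,Dysarthria
misc_neurological,Asterixis
misc_neurological,Gait disturbance
misc_neurological,Nystagmus
liver_dysfunction,Hepatic failure
liver_dysfunction,Acute hepatic failure
liver_dysfunction,Hepatic function abnormal
liver_dysfunction,Hepatotoxicity
liver_dysfunction,Liver injury
liver_dysfunction,Transaminases increased
kidney_dysfunction,Acute kidney injury
kidney_dysfunction,Renal failure
kidney_dysfunction,Renal impairment
kidney_dysfunction,Blood creatinine increased
kidney_dysfunction,Anuria
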