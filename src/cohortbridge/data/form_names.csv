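# short form code,full form name (UDS-style; extend per deployment)
a1,Subject Demographics
a2,Informant Demographics
a3,Subject Family History
a4,Subject Medications
a5,Subject Health History
b1,Physical Evaluation
b4,Global Staging - CDR
b5,Neuropsychiatric Inventory Questionnaire (NPI-Q)
b6,Behavioral Assessment - Geriatric Depression Scale
b7,Functional Assessment Scale
b8,Neurological Examination Findings
b9,Clinician Judgment of Symptoms
c1,Neuropsychological Battery Summary Scores
c2,Neuropsychological Battery Scores
d1,Clinician Diagnosis
d2,Clinician-assessed Medical Conditions
np,Neuropathology
mri,MRI Imaging Summary
csf,CSF Biomarkers
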