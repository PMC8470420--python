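id,age_years,lesion_onset_years,n_sessions,nli_label,ais,group,motor_modality,gender
Subj01,43,26.82,10,T4,A,Motor,EKSO,M
Subj02,37,8.83,10,T4,A,Motor+MI,EKSO,M
Subj03,54,30.05,10,L1,D,Motor,EKSO,M
Subj04,65,29.05,10,T6,A,Motor+MI,EKSO,M
Subj05,44,18.24,8,T6,A,Motor,EKSO,M
Subj06,44,28.31,8,T7,A,Motor,EKSO,M
Subj07,65,29.35,10,T4,A,Motor+MI,EKSO,M
Subj08,57,1.63,10,C5,C,Motor,EKSO,M
Subj09,44,27.40,8,T4,A,Motor+MI,Mobilisation,M
Subj10,65,29.54,9,T6,A,Motor,Mobilisation,M
Subj11,54,30.58,9,L1,D,Motor+MI,Mobilisation,M
Subj12,39,5.58,9,T7,A,Motor,Mobilisation,M
Subj13,44,26.58,8,T6,A,Motor,Mobilisation,F
Subj14,49,15.64,10,T4,A,Motor+MI,Mobilisation,F
Subj15,65,10.64,10,T5,A,Motor+MI,Mobilisation,M
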