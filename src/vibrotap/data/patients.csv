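id,age_range,disease_duration_months,etiology,handedness,diagnosis_stability,diagnosis_crsr,diagnosis_fdgpet,vt2_pct,rejected_vt2,vt3_pct,rejected_vt3,note
MCS-1,40-45,60,TBI,right,4/6,MCS-,MCS,100,3,70,1,
MCS-2,20-25,40,TBI,left,6/6,MCS-,MCS,20,1,,,
MCS-3,55-60,8,anoxia,right,1/6,MCS-,MCS,25,42,,,
MCS-4,55-60,70,TBI,unknown,4/6,MCS-,MCS,10,257,,,
UWS-1,65-70,3,hemorrhage,right,4/4,UWS,MCS,0,3,,,
UWS-2,30-35,9,TBI,left,5/5,UWS,MCS,20,3,,,
UWS-3,55-60,6,anoxia,unknown,5/5,UWS,UWS,75,0,,,very high amplitude response
UWS-4,20-25,15,anoxia,unknown,6/6,UWS,UWS,10,51,,,
UWS-5,45-50,6,anoxia,right,6/6,UWS,UWS,0,23,,,
UWS-6,65-70,5,anoxia,left,7/7,UWS,UWS,0,21,,,
UWS-7,40-45,26,anoxia,right,6/6,UWS,UWS,40,480,,,artifacted by mechanical artifact
UWS-8,30-35,13,TBI,right,6/6,UWS,UWS,10,0,,,
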