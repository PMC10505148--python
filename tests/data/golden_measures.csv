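participant_id,task,modality,measure,raw,log,n_tokens,missing_reason
P01,AMR,in_person,vot_cov_voiceless,0.15058465048420816,-1.8932298912264027,10,
P01,AMR,in_person,vowel_duration_cov,0.171495652615382,-1.7631973618788845,10,
P01,AMR,in_person,formant_dispersion_20,,,0,no_formants
P01,AMR,in_person,formant_dispersion_change,,,0,no_formants
P01,AMR,in_person,speech_rate_cov,,,2,insufficient_tokens
P01,AMR,in_person,speech_rate_mean,3.3333333333333335,1.2039728043259361,2,
P01,AMR,in_person,syllable_cov,0.11941759771498102,-2.125128704336091,10,
P01,AMR,in_person,intersyllable_cov,0.20573779994945485,-1.5811527366899083,8,
P02,READ,in_person,vot_cov_voiceless,,,3,insufficient_tokens
P02,READ,in_person,vot_cov_voiced,,,2,insufficient_tokens
P02,READ,in_person,vowel_duration_cov,0.07917884896521812,-2.536046074348207,5,
P02,READ,in_person,formant_dispersion_20,,,0,no_formants
P02,READ,in_person,formant_dispersion_change,,,0,no_formants
P02,READ,in_person,vowel_overlap,,,5,insufficient_tokens
P02,READ,in_person,speech_rate_cov,,,2,insufficient_tokens
P02,READ,in_person,speech_rate_mean,5.090497737556561,1.6273756131207677,2,
P02,READ,in_person,pause_rate,0.5,-0.6931471805599453,1,
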