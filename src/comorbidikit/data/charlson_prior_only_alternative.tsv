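method	category
charlson_deyo	congestive_heart_failure
charlson_deyo	myocardial_infarction
charlson_deyo	cerebrovascular_disease
charlson_romano	congestive_heart_failure
charlson_romano	myocardial_infarction
charlson_romano	cerebrovascular_disease
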