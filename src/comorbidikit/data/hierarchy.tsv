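method	dominant	suppressed
charlson_deyo	diabetes_with_complications	diabetes
charlson_deyo	moderate_severe_liver_disease	mild_liver_disease
charlson_deyo	metastatic_solid_tumor	any_malignancy
charlson_romano	diabetes_with_complications	diabetes
charlson_romano	moderate_severe_liver_disease	mild_liver_disease
charlson_romano	metastatic_solid_tumor	any_malignancy
elixhauser	diabetes_complicated	diabetes_uncomplicated
elixhauser	metastatic_cancer	solid_tumor
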