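category	drg
congestive_heart_failure	103
congestive_heart_failure	104
congestive_heart_failure	105
congestive_heart_failure	106
congestive_heart_failure	107
congestive_heart_failure	108
congestive_heart_failure	109
congestive_heart_failure	112
congestive_heart_failure	115
congestive_heart_failure	116
congestive_heart_failure	117
congestive_heart_failure	118
congestive_heart_failure	121
congestive_heart_failure	122
congestive_heart_failure	123
congestive_heart_failure	124
congestive_heart_failure	125
congestive_heart_failure	126
congestive_heart_failure	127
congestive_heart_failure	129
congestive_heart_failure	132
congestive_heart_failure	133
congestive_heart_failure	134
congestive_heart_failure	138
congestive_heart_failure	139
congestive_heart_failure	140
congestive_heart_failure	143
congestive_heart_failure	144
congestive_heart_failure	145
cardiac_arrhythmias	103
cardiac_arrhythmias	104
cardiac_arrhythmias	105
cardiac_arrhythmias	106
cardiac_arrhythmias	107
cardiac_arrhythmias	108
cardiac_arrhythmias	109
cardiac_arrhythmias	112
cardiac_arrhythmias	115
cardiac_arrhythmias	116
cardiac_arrhythmias	117
cardiac_arrhythmias	118
cardiac_arrhythmias	121
cardiac_arrhythmias	122
cardiac_arrhythmias	123
cardiac_arrhythmias	124
cardiac_arrhythmias	125
cardiac_arrhythmias	126
cardiac_arrhythmias	127
cardiac_arrhythmias	129
cardiac_arrhythmias	132
cardiac_arrhythmias	133
cardiac_arrhythmias	134
cardiac_arrhythmias	138
cardiac_arrhythmias	139
cardiac_arrhythmias	140
cardiac_arrhythmias	143
cardiac_arrhythmias	144
cardiac_arrhythmias	145
valvular_disease	103
valvular_disease	104
valvular_disease	105
valvular_disease	106
valvular_disease	107
valvular_disease	108
valvular_disease	109
valvular_disease	112
valvular_disease	115
valvular_disease	116
valvular_disease	117
valvular_disease	118
valvular_disease	121
valvular_disease	122
valvular_disease	123
valvular_disease	124
valvular_disease	125
valvular_disease	126
valvular_disease	127
valvular_disease	129
valvular_disease	132
valvular_disease	133
valvular_disease	134
valvular_disease	138
valvular_disease	139
valvular_disease	140
valvular_disease	143
valvular_disease	144
valvular_disease	145
hypertension	103
hypertension	104
hypertension	105
hypertension	106
hypertension	107
hypertension	108
hypertension	109
hypertension	112
hypertension	115
hypertension	116
hypertension	117
hypertension	118
hypertension	121
hypertension	122
hypertension	123
hypertension	124
hypertension	125
hypertension	126
hypertension	127
hypertension	129
hypertension	132
hypertension	133
hypertension	134
hypertension	138
hypertension	139
hypertension	140
hypertension	143
hypertension	144
hypertension	145
pulmonary_circulation	103
pulmonary_circulation	104
pulmonary_circulation	105
pulmonary_circulation	106
pulmonary_circulation	107
pulmonary_circulation	108
pulmonary_circulation	109
pulmonary_circulation	112
pulmonary_circulation	115
pulmonary_circulation	116
pulmonary_circulation	117
pulmonary_circulation	118
pulmonary_circulation	121
pulmonary_circulation	122
pulmonary_circulation	123
pulmonary_circulation	124
pulmonary_circulation	125
pulmonary_circulation	126
pulmonary_circulation	127
pulmonary_circulation	129
pulmonary_circulation	132
pulmonary_circulation	133
pulmonary_circulation	134
pulmonary_circulation	138
pulmonary_circulation	139
pulmonary_circulation	140
pulmonary_circulation	143
pulmonary_circulation	144
pulmonary_circulation	145
pulmonary_circulation	075
pulmonary_circulation	076
pulmonary_circulation	077
pulmonary_circulation	078
pulmonary_circulation	079
pulmonary_circulation	080
pulmonary_circulation	085
pulmonary_circulation	087
pulmonary_circulation	088
pulmonary_circulation	089
pulmonary_circulation	090
pulmonary_circulation	091
pulmonary_circulation	092
pulmonary_circulation	096
pulmonary_circulation	097
pulmonary_circulation	101
pulmonary_circulation	102
peripheral_vascular	110
peripheral_vascular	111
peripheral_vascular	130
peripheral_vascular	131
chronic_pulmonary	075
chronic_pulmonary	076
chronic_pulmonary	077
chronic_pulmonary	078
chronic_pulmonary	079
chronic_pulmonary	080
chronic_pulmonary	085
chronic_pulmonary	087
chronic_pulmonary	088
chronic_pulmonary	089
chronic_pulmonary	090
chronic_pulmonary	091
chronic_pulmonary	092
chronic_pulmonary	096
chronic_pulmonary	097
chronic_pulmonary	101
chronic_pulmonary	102
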