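drg
075
076
077
104
105
106
107
108
110
111
112
461
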