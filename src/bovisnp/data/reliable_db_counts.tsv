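breed	reliable_records	error_records
PolishRed	31562	4381
PolishHF	24945	1164
Hereford	28194	1202
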