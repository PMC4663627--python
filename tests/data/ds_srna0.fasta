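>ds_srna0_positive 5'->3' positive strand of the perfect reference duplex
CGUACGCGGAAUACUUCGAUU
>ds_srna0_negative_as_printed negative strand written 3'->5' in some sources; do not pair directly
UUGCAUGCGCCUUAUGAAGCU
>ds_srna0_negative re-oriented 5'->3' negative strand used by duplex operations
UCGAAGUAUUCCGCGUACGUU
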