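>s1
AAAAAAAAAA
>s2
AAAAAAAAAT
>s3
AAAAAAAATT
>s4
CCCCAAAAAA
>s5
CCCCAAAAAT
>s6
AAAAAAAAAA
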