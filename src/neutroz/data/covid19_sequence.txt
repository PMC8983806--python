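# Covid-19 worked-example event sequence (n = 12).
# A = reduction in deaths, B = increase in vaccinations; read left to right.
A A B A B A B B A B A B
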