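# Ordered suffix-rewrite rules: suffix<TAB>replacement. First match wins.
# Identity rules guard common suffixes from over-stripping.
ies	y
sses	ss
xes	x
ches	ch
shes	sh
ing
ed
ss	ss
us	us
is	is
s
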