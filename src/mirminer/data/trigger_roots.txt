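# relation-trigger root forms, one per line
regulate
up-regulate
down-regulate
express
suppress
inhibit
target
induce
associate
correlate
modulate
change
increase
decrease
mediate
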