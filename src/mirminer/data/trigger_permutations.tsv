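# allowed root combinations for compound triggers: root <TAB> root
# (pairs such as target + up-regulate are deliberately absent: they are
# not logical relation triggers and must not be combined)
change	express
regulate	express
increase	express
decrease	express
suppress	express
inhibit	express
modulate	express
correlate	express
associate	express
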