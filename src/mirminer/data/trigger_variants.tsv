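# word variations: root <TAB> variant <TAB> variant ...
regulate	regulates	regulated	regulation	regulatory
up-regulate	up-regulates	up-regulated	up-regulation	upregulate	upregulated	upregulation
down-regulate	down-regulates	down-regulated	down-regulation	downregulate	downregulated	downregulation
express	expresses	expressed	expression
suppress	suppresses	suppressed	suppression	suppressor
inhibit	inhibits	inhibited	inhibition	inhibitor
target	targets	targeted	targeting
induce	induces	induced	induction
associate	associates	associated	association
correlate	correlates	correlated	correlation
modulate	modulates	modulated	modulation
change	changes	changed
increase	increases	increased
decrease	decreases	decreased
mediate	mediates	mediated
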