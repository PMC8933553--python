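# Irregular / non-plural lemma pairs used by simplify_tokens.
# Regular plurals are handled by suffix rules; this table pins the
# inflected medical vocabulary that the rules cannot derive.
# form<TAB>lemma
increased	increase
increasing	increase
decreased	decrease
decreasing	decrease
elevated	elevate
reduced	reduce
worsened	worsen
swollen	swell
feet	foot
teeth	tooth
men	man
women	woman
children	child
mice	mouse
vertebrae	vertebra
bacteria	bacterium
criteria	criterion
phenomena	phenomenon
oedema	edema
anaemia	anemia
diarrhoea	diarrhea
haemorrhage	hemorrhage
vomited	vomit
vomiting	vomit
itching	itch
bleeding	bleed
swelling	swell
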