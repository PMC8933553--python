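# Auxiliary words/phrases stripped from adverse-event terms before
# dictionary lookup: laterality markers, study-phase labels, and
# time-frame patterns. One pattern per line, matched case-insensitively
# as whole token spans. <number> matches an integer or decimal;
# <time-unit> matches a clock/calendar unit word.
left
right
bilateral
baseline phase
treatment phase
titration phase
maintenance phase
follow-up phase
double-blind phase
open-label phase
first intervention
second intervention
cycle <number>
week <number>
day <number>
grade <number>
for <number> <time-unit>
after <number> <time-unit>
at <number> <time-unit>
within <number> <time-unit>
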