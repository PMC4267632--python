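# Nearest-neighbor energy bundle (reduced model). Units: kcal/mol.
# Scalars: key value. Tables: <table> <key(s)> <value>.

au_gu_end_penalty 0.5
mbl_closure 3.4
mbl_branch 0.4
mbl_unpaired 0.0
gap_penalty 0.4
domain_opening 0.5
domain_elongation 0.1
internal_asymmetry 0.6
internal_asymmetry_cap 3.0
loop_log_coeff 1.1
max_internal_side 20
max_stackII_extension 5
min_hairpin 3

stack AU AU -0.9
stack AU CG -2.2
stack AU GC -2.1
stack AU GU -0.6
stack AU UA -1.1
stack AU UG -1.4
stack CG AU -2.1
stack CG CG -3.3
stack CG GC -2.4
stack CG GU -1.4
stack CG UA -2.1
stack CG UG -2.1
stack GC AU -2.4
stack GC CG -3.4
stack GC GC -3.3
stack GC GU -1.5
stack GC UA -2.2
stack GC UG -2.5
stack GU AU -1.3
stack GU CG -2.5
stack GU GC -2.1
stack GU GU -0.5
stack GU UA -1.4
stack GU UG -0.5
stack UA AU -1.3
stack UA CG -2.4
stack UA GC -2.1
stack UA GU -1.0
stack UA UA -0.9
stack UA UG -1.3
stack UG AU -1.0
stack UG CG -1.5
stack UG GC -1.4
stack UG GU 0.5
stack UG UA -0.6
stack UG UG -0.5

hairpin 3 5.4
hairpin 4 5.6
hairpin 5 5.7
hairpin 6 5.4
hairpin 7 6.0
hairpin 8 5.5
hairpin 9 6.4
hairpin 10 6.5
hairpin 11 6.6
hairpin 12 6.7
hairpin 13 6.8
hairpin 14 6.9
hairpin 15 6.9
hairpin 16 7.0
hairpin 17 7.1
hairpin 18 7.1
hairpin 19 7.2
hairpin 20 7.3
hairpin 21 7.3
hairpin 22 7.4
hairpin 23 7.4
hairpin 24 7.5
hairpin 25 7.5
hairpin 26 7.6
hairpin 27 7.6
hairpin 28 7.6
hairpin 29 7.7
hairpin 30 7.7

internal 2 1.5
internal 3 1.6
internal 4 1.7
internal 5 1.8
internal 6 2.0
internal 7 2.2
internal 8 2.3
internal 9 2.4
internal 10 2.5
internal 11 2.6
internal 12 2.7
internal 13 2.8
internal 14 2.9
internal 15 2.9
internal 16 3.0
internal 17 3.1
internal 18 3.1
internal 19 3.2
internal 20 3.3
internal 21 3.3
internal 22 3.4
internal 23 3.4
internal 24 3.5
internal 25 3.5
internal 26 3.6
internal 27 3.6
internal 28 3.6
internal 29 3.7
internal 30 3.7

bulge 1 3.8
bulge 2 2.8
bulge 3 3.2
bulge 4 3.6
bulge 5 4.0
bulge 6 4.4
bulge 7 4.6
bulge 8 4.7
bulge 9 4.8
bulge 10 4.9
bulge 11 5.0
bulge 12 5.1
bulge 13 5.2
bulge 14 5.3
bulge 15 5.3
bulge 16 5.4
bulge 17 5.5
bulge 18 5.5
bulge 19 5.6
bulge 20 5.7
bulge 21 5.7
bulge 22 5.8
bulge 23 5.8
bulge 24 5.9
bulge 25 5.9
bulge 26 6.0
bulge 27 6.0
bulge 28 6.0
bulge 29 6.1
bulge 30 6.1
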