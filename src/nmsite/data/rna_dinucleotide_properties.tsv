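dinucleotide	stack_dG37	stack_dH	stack_dS
AA	-0.93	-6.82	-18.99
AC	-2.24	-11.40	-29.53
AG	-2.08	-10.48	-27.08
AU	-1.10	-9.38	-26.70
CA	-2.11	-10.44	-26.86
CC	-3.26	-13.39	-32.66
CG	-2.36	-10.64	-26.70
CU	-2.08	-10.48	-27.08
GA	-2.35	-12.44	-32.53
GC	-3.42	-14.88	-36.95
GG	-3.26	-13.39	-32.66
GU	-2.24	-11.40	-29.53
UA	-1.33	-7.69	-20.51
UC	-2.35	-12.44	-32.53
UG	-2.11	-10.44	-26.86
UU	-0.93	-6.82	-18.99
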