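protein	constellation	constellation_ddG	summed_individual_ddG	printed_cooperativity
beta2_appendage	B759_B804_B815	9.7	25.8	-16.2
beta2_appendage	B804_B812_B815	14.1	25.3	-11.2
beta2_appendage	B842_B846_B847	3.8	15.1	-11.3
beta2_appendage	B842_B846_B849	-2.4	12.3	-14.7
beta2_appendage	B842_B847_B849	1.5	15.2	-13.6
beta2_appendage	B846_B847_B849	2.3	16.1	-13.8
terminal_domain	Y159_Y161_Y164	-1.4	14.7	-16.1
terminal_domain	Z140_Z187_Z189	3.7	19.0	-15.3
alpha_appendage_sandwich	A761_A763	-15.1	7.7	-22.8
terminal_domain_alpha_sandwich	Y161_Y164	-13.8	10.0	-23.8
terminal_domain_alpha_sandwich	Z140_Z189	-8.9	13.0	-21.9
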