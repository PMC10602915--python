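key	expected	tolerance	note
cell_NUN_U_percent	87.5	0.05	misdecoding frequency of the NUN/U cell (56/64)
cell_NCN_C_percent	91.7	0.05	NCN/C cell (44/48)
cell_NUN_C_percent	75.0	0.05	NUN/C cell
cell_NCN_U_percent	53.8	0.05	NCN/U cell
cell_NAN_A_percent	22.6	0.05	NAN/A cell
cell_NGN_G_percent	17.0	0.05	NGN/G cell
column_avg_NUN	9.4	0.05	mean misincorporating amino acids per NUN codon
column_avg_NCN	7.6	0.05	mean per NCN codon
column_avg_NAN	4.2	0.05	mean per NAN codon
column_avg_NGN	2.3	0.05	mean per NGN codon
rule1_percent	74.6	0.05	rule-1 coverage (191/256)
rule2_percent	66.7	0.05	rule-2 coverage (18/27)
other_percent	17.9	0.05	remaining combinations (157/876)
rule2_second_gu_percent	78.6	0.05	second-position G-U subset (11/14)
rule2_first_gu_percent	53.8	0.05	first-position G-U subset (7/13)
class_1_percent	49.4	1.0	1-mismatch class frequency
class_2_percent	18.7	1.0	2-mismatch class frequency
class_3_percent	14.7	1.0	3-mismatch class frequency
class_1/2_percent	65.6	1.0	1/2-mismatch class frequency
class_2/3_percent	29.5	1.0	2/3-mismatch class frequency
class_1/2/3_percent	40.5	1.0	1/2/3-mismatch class frequency
three_mismatch_events	31	0	positive three-mismatch combinations
three_mismatch_NUN_NCN	21	0	of which in NUN/NCN columns
diversity_U	70.1	0.8	group U diversity index
diversity_C	65.5	0.7	group C diversity index
diversity_A	1500	15	group A diversity index
diversity_G	6680	67	group G diversity index
diversity_Y	507	5.1	group Y (U and C combined)
pair_Y/C	191	1.9	Tyr/Cys pair index
pair_H/R	83.2	0.9	His/Arg pair index
pair_Q/R	151	1.5	Gln/Arg pair index
pair_N/S	18.3	0.2	Asn/Ser pair index
pair_H/Y	148	1.5	His/Tyr pair index
pair_S/G	3.35	0.04	Ser/Gly pair index
pair_mean	259	2.6	mean over the 190 unordered pairs
pam_within_U	-1.9	0.05	PAM30 within-group-U average
pam_within_C	-1.5	0.05	PAM30 within-group-C average
pam_within_A	-3.6	0.05	PAM30 within-group-A average
pam_within_G	-9.7	0.05	PAM30 within-group-G average
pam_between_U_C	-6.1	0.05	PAM30 U-C cross-group average
pam_overall	-6.5	0.05	PAM30 average over all 190 pairs
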