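# Literature-reported hot-spot predictions for four shared residues of the
# TCF4 / ICAT / beta-catenin-family complexes 1TH1, 1JPP and 3OUX, with the
# experimentally derived categorical labels (positive class: Strong).
# Numeric predictions are ddG estimates in kcal/mol (call threshold 1.5);
# categorical predictions are the methods' published binary calls.
# contact_rf is a reference run of the contact-based random-forest method.
complex_id	residue	observed	method	prediction
1TH1	Trp383	Strong	contact_rf	1.06
1TH1	Arg386	Insignificant	contact_rf	2.61
1TH1	Lys435	Insignificant	contact_rf	1.76
1TH1	His470	Insignificant	contact_rf	2.40
1JPP	Trp383	Intermediate	contact_rf	0.325
1JPP	Arg386	Strong	contact_rf	1.65
1JPP	Lys435	Intermediate	contact_rf	1.12
1JPP	His470	Insignificant	contact_rf	0.99
3OUX	Trp383	Insignificant	contact_rf	1.87
3OUX	Arg386	Intermediate	contact_rf	2.38
3OUX	Lys435	Strong	contact_rf	2.65
3OUX	His470	Strong	contact_rf	3.90
1TH1	Trp383	Strong	robetta	1.22
1TH1	Arg386	Insignificant	robetta	1.00
1TH1	Lys435	Insignificant	robetta	1.60
1TH1	His470	Insignificant	robetta	0.50
1JPP	Trp383	Intermediate	robetta	0.93
1JPP	Arg386	Strong	robetta	0.50
1JPP	Lys435	Intermediate	robetta	0.50
1JPP	His470	Insignificant	robetta	0.47
3OUX	Trp383	Insignificant	robetta	2.58
3OUX	Arg386	Intermediate	robetta	2.38
3OUX	Lys435	Strong	robetta	1.69
3OUX	His470	Strong	robetta	3.05
1TH1	Trp383	Strong	hotpoint	Hot
1TH1	Arg386	Insignificant	hotpoint	NonHot
1TH1	Lys435	Insignificant	hotpoint	NonHot
1TH1	His470	Insignificant	hotpoint	Hot
1JPP	Trp383	Intermediate	hotpoint	NonHot
1JPP	Arg386	Strong	hotpoint	NonHot
1JPP	Lys435	Intermediate	hotpoint	NonHot
1JPP	His470	Insignificant	hotpoint	Hot
3OUX	Trp383	Insignificant	hotpoint	Hot
3OUX	Arg386	Intermediate	hotpoint	NonHot
3OUX	Lys435	Strong	hotpoint	NonHot
3OUX	His470	Strong	hotpoint	Hot
1TH1	Trp383	Strong	kfc2a	NonHot
1TH1	Arg386	Insignificant	kfc2a	Hot
1TH1	Lys435	Insignificant	kfc2a	NonHot
1TH1	His470	Insignificant	kfc2a	Hot
1JPP	Trp383	Intermediate	kfc2a	NonHot
1JPP	Arg386	Strong	kfc2a	Hot
1JPP	Lys435	Intermediate	kfc2a	NonHot
1JPP	His470	Insignificant	kfc2a	NonHot
3OUX	Trp383	Insignificant	kfc2a	Hot
3OUX	Arg386	Intermediate	kfc2a	Hot
3OUX	Lys435	Strong	kfc2a	NonHot
3OUX	His470	Strong	kfc2a	Hot
1TH1	Trp383	Strong	kfc2b	NonHot
1TH1	Arg386	Insignificant	kfc2b	Hot
1TH1	Lys435	Insignificant	kfc2b	NonHot
1TH1	His470	Insignificant	kfc2b	NonHot
1JPP	Trp383	Intermediate	kfc2b	NonHot
1JPP	Arg386	Strong	kfc2b	Hot
1JPP	Lys435	Intermediate	kfc2b	NonHot
1JPP	His470	Insignificant	kfc2b	NonHot
3OUX	Trp383	Insignificant	kfc2b	Hot
3OUX	Arg386	Intermediate	kfc2b	Hot
3OUX	Lys435	Strong	kfc2b	NonHot
3OUX	His470	Strong	kfc2b	NonHot
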