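# Adjustable TG:VLDL-C factor lookup, standard variant (TG < 400 mg/dL).
# Rows: half-open TG strata [tg_lo, tg_hi) in mg/dL; columns: half-open
# non-HDL-C strata <100, 100-129, 130-159, 160-189, 190-219, >=220 mg/dL
# (the last stratum absorbs all larger values). Cells are the divisor f such
# that estimated VLDL-C = TG/f. Transcribed from the published 180-cell
# adjustable-factor table (Martin et al., JAMA 2013), restricted to its 29 TG
# strata below 400 mg/dL; the first TG stratum is widened to start at 0.
tg_lo	tg_hi	nonhdl_lt_100	nonhdl_100_129	nonhdl_130_159	nonhdl_160_189	nonhdl_190_219	nonhdl_ge_220
0	50	3.5	3.4	3.3	3.3	3.2	3.1
50	57	4.0	3.9	3.7	3.6	3.6	3.4
57	62	4.3	4.1	4.0	3.9	3.8	3.6
62	67	4.5	4.3	4.1	4.0	3.9	3.9
67	72	4.7	4.4	4.3	4.2	4.1	3.9
72	76	4.8	4.6	4.4	4.2	4.2	4.1
76	80	4.9	4.6	4.5	4.3	4.3	4.2
80	84	5.0	4.8	4.6	4.4	4.3	4.2
84	88	5.1	4.8	4.6	4.5	4.4	4.3
88	93	5.2	4.9	4.7	4.6	4.4	4.3
93	97	5.3	5.0	4.8	4.6	4.5	4.4
97	101	5.4	5.1	4.8	4.7	4.5	4.3
101	106	5.5	5.2	5.0	4.7	4.6	4.5
106	111	5.6	5.3	5.0	4.8	4.6	4.5
111	116	5.7	5.4	5.1	4.9	4.7	4.5
116	121	5.8	5.5	5.2	5.0	4.8	4.6
121	127	6.0	5.5	5.3	5.0	4.8	4.6
127	133	6.1	5.7	5.3	5.1	4.9	4.7
133	139	6.2	5.8	5.4	5.2	5.0	4.7
139	147	6.3	5.9	5.6	5.3	5.0	4.8
147	155	6.5	6.0	5.7	5.4	5.1	4.8
155	164	6.7	6.2	5.8	5.4	5.2	4.9
164	174	6.8	6.3	5.9	5.5	5.3	5.0
174	186	7.0	6.5	6.0	5.7	5.4	5.1
186	202	7.3	6.7	6.2	5.8	5.5	5.2
202	221	7.6	6.9	6.4	6.0	5.6	5.3
221	248	8.0	7.2	6.6	6.2	5.9	5.4
248	293	8.5	7.6	7.0	6.5	6.1	5.6
293	400	9.5	8.3	7.5	7.0	6.5	5.9
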