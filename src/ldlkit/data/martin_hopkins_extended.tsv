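# Adjustable TG:VLDL-C factor lookup, extended variant (TG 400-799 mg/dL).
# Same column strata as the standard table. The original extended-factor
# cells (Sajja et al., JAMA Netw Open 2021) were not available for
# transcription; these cells are a monotone reconstruction spanning the
# standard table's top row and the published 180-cell table's TG>=400 row
# (11.9 ... 6.7). Replace with the published cells where exactness matters.
tg_lo	tg_hi	nonhdl_lt_100	nonhdl_100_129	nonhdl_130_159	nonhdl_160_189	nonhdl_190_219	nonhdl_ge_220
400	450	9.8	8.6	7.7	7.1	6.7	6.0
450	500	10.0	8.8	7.9	7.3	6.8	6.1
500	550	10.3	9.0	8.1	7.4	6.9	6.2
550	600	10.5	9.2	8.2	7.6	7.0	6.3
600	650	10.7	9.4	8.4	7.7	7.2	6.4
650	700	11.0	9.6	8.5	7.8	7.3	6.5
700	750	11.3	9.8	8.7	8.0	7.4	6.6
750	800	11.9	10.0	8.8	8.1	7.5	6.7
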