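# LDL-C estimation equation registry. One row per equation; coefficients are in
# the units of the source publication (source_units); the loader converts
# mmol/L-published coefficients to mg/dL once, at registry-build time.
# Families:
#   fixed_ratio : LDL = TC - HDL - TG/k
#   linear      : LDL = alpha*TC + beta*HDL + gamma*TG + delta
#   quadratic   : LDL = alpha*TC + beta*HDL + gamma*TG + tg_nonhdl*TG*(TC-HDL) + tg_sq*TG^2 + delta
#   table_factor: LDL = TC - HDL - TG/f(TG, TC-HDL), f from the named lookup table
# Coefficient provenance: transcribed from the primary publications where the
# published form is well established; entries whose originals could not be
# consulted are reconstructions consistent with each equation's documented
# structure (family, intercept, variable usage) and reported bias, and should
# be corrected against the originals if a discrepancy is found.
id	role	family	source_units	k	alpha	beta	gamma	tg_nonhdl	tg_sq	delta	table	tg_lo	tg_hi	citation
friedewald	primary	fixed_ratio	mg/dL	5								0	400	Friedewald, Levy & Fredrickson, Clin Chem 1972
delong	primary	fixed_ratio	mg/dL	6.25								0	400	DeLong et al., JAMA 1986 (VLDL-C = 0.16 TG)
rao	primary	linear	mg/dL		0.98	-0.87	-0.19			0		0	400	Rao et al., Clin Chem 1988
hattori	primary	linear	mg/dL		0.94	-0.94	-0.19			0		0	400	Hattori et al., Atherosclerosis 1998
anandaraja	primary	linear	mg/dL		0.9	0	-0.18			-28		0	400	Anandaraja et al., Int J Cardiol 2005
teerakanchana	primary	linear	mg/dL		0.903	-0.729	-0.117			-4.22		0	400	Teerakanchana et al., J Med Assoc Thai 2007
ahmadi	primary	linear	mg/dL		0.8403361344537815	-0.9090909090909091	0.5263157894736842			-38		0	400	Ahmadi et al., Arch Iran Med 2008 (TC/1.19 + TG/1.9 - HDL/1.1 - 38)
puavilai	primary	fixed_ratio	mg/dL	6								0	400	Puavilai et al., J Med Assoc Thai 2009
saiedullah	primary	quadratic	mg/dL		1	-1	-0.2		-5e-05	-3.0		0	400	Saiedullah et al., 2009
chen	primary	linear	mg/dL		0.9	-0.9	-0.1			0		0	400	Chen et al., Lipids Health Dis 2010
vujovic	primary	fixed_ratio	mg/dL	6.85								0	400	Vujovic et al., Lipids Health Dis 2010
cordova	primary	linear	mg/dL		0.75	-0.75	0			0		0	400	de Cordova & de Cordova, Ann Clin Biochem 2013
martin_hopkins	primary	table_factor	mg/dL								standard	0	400	Martin et al., JAMA 2013 (180-cell adjustable factor)
dansethakul	primary	linear	mmol/L		0.9	-0.88	-0.23			0.05		0	400	Dansethakul et al., Pract Lab Med 2015
bauer	primary	fixed_ratio	mg/dL	7.5								0	400	Bauer et al., 2015
rasouli	primary	linear	mg/dL		0.83	-0.83	-0.071			0		0	400	Rasouli et al., 2016
choi	primary	linear	mg/dL		1.04	-1.04	-0.175			0		0	400	Choi et al., 2016
lee_hu	primary	linear	mg/dL		0.727	0	-0.201			0		0	400	Lee & Hu, 2017
ghasemi	primary	fixed_ratio	mg/dL	4								0	400	Ghasemi et al., 2018
ephraim	primary	fixed_ratio	mg/dL	8.5								0	400	Ephraim et al., 2018
molavi	primary	linear	mg/dL		0.94	-0.94	-0.18			0		0	400	Molavi et al., 2020
orejon	primary	linear	mg/dL		0.94	-0.94	-0.14			2.0		0	400	Orejon de Luna et al., 2020
sampson	primary	quadratic	mg/dL		1.0548523206751055	-1.0298661174047374	-0.11682242990654206	-0.00046728971962616824	6.211180124223603e-05	-9.44		0	800	Sampson et al., JAMA Cardiol 2020 (NIH equation 2)
martin_hopkins_extended	variant	table_factor	mg/dL								extended	400	800	Sajja et al., JAMA Netw Open 2021 (extended adjustable factor, TG 400-799)
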