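# Spectral tuning-site substitutions with experimentally measured lambda-max shifts (nm; negative = blue).
# Sites are numbered by bovine rhodopsin.  Every entry has |shift| >= 5 nm.  The table is user-replaceable
# config: each magnitude carries its literature source.  Rows sharing an interaction_group act non-additively;
# when all members co-occur, combined_shift (carried on the group's rows) replaces the member sum.
family	site	from_res	to_res	shift_nm	reversible	interaction_group	combined_shift	source
LWS	164	S	A	-7	1			Yokoyama & Radlwimmer 1998, five-sites mutagenesis
LWS	164	S	P	-11	1			Ward et al. 2008, killifish/guppy LWS P180
LWS	181	H	Y	-28	1			Yokoyama & Radlwimmer 1998, five-sites mutagenesis
LWS	261	Y	F	-8	1			Yokoyama & Radlwimmer 1998, five-sites mutagenesis
LWS	269	T	A	-15	1			Yokoyama & Radlwimmer 1998, five-sites mutagenesis
LWS	292	A	S	-27	1			Yokoyama & Radlwimmer 1998, five-sites mutagenesis
Rh2	122	E	Q	-20	1			Yokoyama et al. 1999, Rh2 E122Q mutagenesis (~20 nm blue)
Rh2	97	S	T	-6	1			Takenaka & Yokoyama 2007, Rh2 site 97
Rh2	207	M	L	-6	1			Yokoyama & Jia 2020 compilation, Rh2 M207L
SWS2	94	A	C	-14	1	sws2_94_265	-32	Yokoyama & Tada 2003, bluefin killifish SWS2
SWS2	265	W	Y	-19	1	sws2_94_265	-32	Yokoyama & Tada 2003, bluefin killifish SWS2 (pair gives 32 nm, less than the 33 nm sum)
SWS2	118	T	G	-9	1			Chinen et al. 2005, SWS2 site 118
SWS2	97	S	C	-6	1			Yokoyama & Tada 2003, SWS2 site 97
Rh1	83	D	N	-6	1			Nakayama & Khorana 1991; fish Rh1 compilation
Rh1	122	E	Q	-20	1			Yokoyama et al. 1999, Rh1/Rh2 E122Q
Rh1	261	F	Y	8	1			Chan et al. 1992, Rh1 F261Y red shift
Rh1	292	A	S	-10	1			Fasick & Robinson 1998, Rh1 A292S
SWS1	114	A	S	-5	1			Shi & Yokoyama 2003, SWS1 compilation
SWS1	118	S	A	-5	1			Shi & Yokoyama 2003, SWS1 compilation
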