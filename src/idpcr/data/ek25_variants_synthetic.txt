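# Synthetic (EK)25 blockiness ladder -- 30 sequence variants, 50 residues each,
# exactly 25 E and 25 K. Variant 1 is the strictly alternating (EK)25, variant 30
# the E25K25 diblock; variants 2..29 interpolate deterministically between them
# with ~evenly spaced, monotonically decreasing SCD (sequence charge decoration,
# scd = (1/N) * sum_{m>n} sigma_m sigma_n sqrt(m-n), formal charges sigma: E=-1, K=+1).
# SYNTHETIC stand-in for the classic 50-residue E/K variant set ordered by
# blockiness; regenerate with idpcr.sequences.build_blockiness_ladder().
# columns: variant_number  scd  sequence
1	-0.413087	EKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEKEK
2	-1.359042	EKKKEKKKEKEEEKKEEEEKEEKEKEEKKKEEEKKEEEKKEKKKKEKEEK
3	-2.303346	EKKKKKKEKKEEEEEKKKEKEKKEKEKKEEKEKEEKEEEEKKKKEEEEEK
4	-3.250997	EEEEEKEEKKEKEKEKEKEEKEKEKEKEKEKEKEKEKKEEKEKKEKKKKK
5	-4.198969	EEEEEEKEKEKEKEKEEKEKEKEKEKEKEKEKEKEKKEKEKEKEKKKKKK
6	-5.154043	EEEEEEKEEKEKEKEKEEKEKEKEKEKEKEKEKKEKEKEKEKKEKKKKKK
7	-6.099078	EEEEEEEKEEKEKEKEKEKEKEEKEKEKKEKEKEKEKEKEKKEKKKKKKK
8	-7.029252	EEEEEEEEKEKEEKEKEKEKEKEKEKEKEKEKEKEKEKKEKEKKKKKKKK
9	-7.979402	EEEEEEEEKEEKEKEEKEKEKEKEKEKEKEKEKKEKEKEKKEKKKKKKKK
10	-8.926953	EEEEEEEEEKEEKEKEKEKEKEEKEKEKKEKEKEKEKEKKEKKKKKKKKK
11	-9.910589	EEEEEEEEEEKEKEEKEKEKEKEKEKEKEKEKEKEKKEKEKKKKKKKKKK
12	-10.768585	EEEEEEEEEEKEEKEKEKEEKEKEKEKEKEKKEKEKEKKEKKKKKKKKKK
13	-11.794816	EEEEEEEEEEEKEEKEKEKEKEKEEKKEKEKEKEKEKKEKKKKKKKKKKK
14	-12.742870	EEEEEEEEEEEKEEKEEKEKEKEKEKEKEKEKEKKEKKEKKKKKKKKKKK
15	-13.640641	EEEEEEEEEEEEKEEKEKEKEEKEKEKKEKEKEKEKKEKKKKKKKKKKKK
16	-14.559934	EEEEEEEEEEEEEKEKEEKEKEKEKEKEKEKEKKEKEKKKKKKKKKKKKK
17	-15.545494	EEEEEEEEEEEEEKEEKEKEEKEKEKEKEKKEKEKKEKKKKKKKKKKKKK
18	-16.419324	EEEEEEEEEEEEEEKEEKEKEKEKEKEKEKEKEKKEKKKKKKKKKKKKKK
19	-17.505495	EEEEEEEEEEEEEEKEEKEEKEKEKEKEKEKKEKEKKKKKKKKKKKKKKK
20	-18.322743	EEEEEEEEEEEEEEEEKEKEKEKEKEKEKEKEKEKKKKKKKKKKKKKKKK
21	-19.324860	EEEEEEEEEEEEEEEEKEEKEKEKEKEKEKKEKEKKKKKKKKKKKKKKKK
22	-20.225121	EEEEEEEEEEEEEEEEEKEKEKEEKEKKEKEKEKKKKKKKKKKKKKKKKK
23	-21.140026	EEEEEEEEEEEEEEEEEKEEKEKEKEKEKEKEKKKKKKKKKKKKKKKKKK
24	-22.114897	EEEEEEEEEEEEEEEEEEKEKEEKEKEKEKKEKKKKKKKKKKKKKKKKKK
25	-23.145582	EEEEEEEEEEEEEEEEEEEKEKEEKEKKEKEKKKKKKKKKKKKKKKKKKK
26	-24.002006	EEEEEEEEEEEEEEEEEEEEKEKEKEKEKEKKKKKKKKKKKKKKKKKKKK
27	-24.917226	EEEEEEEEEEEEEEEEEEEEEKEKEKEKKEKKKKKKKKKKKKKKKKKKKK
28	-25.891328	EEEEEEEEEEEEEEEEEEEEEEKEKEKKEKKKKKKKKKKKKKKKKKKKKK
29	-26.940868	EEEEEEEEEEEEEEEEEEEEEEEKEKEKKKKKKKKKKKKKKKKKKKKKKK
30	-27.842143	EEEEEEEEEEEEEEEEEEEEEEEEEKKKKKKKKKKKKKKKKKKKKKKKKK
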