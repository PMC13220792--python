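# Biological hydrophobicity scale, full position-dependent model
# (translocon-mediated membrane insertion; ΔG_app in kcal/mol).
# Per-residue positional contribution across a segment of length L, with the
# normalized coordinate pos = 9 * (2*i/(L-1) - 1) for i = 0..L-1 (ends at ±9):
#   dG_aa(pos) = a0 * exp(-a1 * pos^2)
#              + a2 * (exp(-a3*(pos-a4)^2) + exp(-a3*(pos+a4)^2))   # W and Y only
# Total for a segment:
#   dG_app = sum_i dG_aa(pos_i)
#          + moment_coef * sqrt( (sum_i dG_i*sin(angle*i))^2 + (sum_i dG_i*cos(angle*i))^2 )
#          + len_c0 + len_c1*L + len_c2*L^2
# provenance: dG prediction server full-model parameter set (calc_dG), v1
const	moment_coef	0.27045
const	helix_angle_deg	100
const	len_c0	9.29274167549645
const	len_c1	-0.64513139783394
const	len_c2	0.00822196628688
const	min_len	9
const	max_len	40
aa	A	0.1267255	0.0215152
aa	C	-0.0765051	0.0994228
aa	D	1.7939795	0.0172643
aa	E	1.4193720	0.0089351
aa	F	-0.2766953	0.0010297
aa	G	0.4813492	0.0047210
aa	H	1.1998590	0.0080127
aa	I	-0.4597384	0.0181495
aa	K	1.8485768	0.0218446
aa	L	-0.4282992	0.0023804
aa	M	-0.0774786	0.0984413
aa	N	1.3266132	0.0092375
aa	P	1.0860888	0.0100568
aa	Q	1.3336109	0.0111996
aa	R	1.6492534	0.0512044
aa	S	0.7023921	0.0077661
aa	T	0.5266550	0.0311973
aa	V	-0.2447218	0.0979201
aa	W	0.2909390	0.0189282	-0.5479140	0.0930222	6.4736619
aa	Y	0.6275249	0.0103896	-0.5744404	0.0947821	6.9164963
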