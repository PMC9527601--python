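cross_id	series	mother_id	mother_s1	mother_s2	father_id	father_s1	father_s2	shared_allele	seed_genotype	count
c1	sc1	M	Sx	S_C1	M	S_C1	Sy	S_C1	Sx/S_C1	0
c1	sc1	M	Sx	S_C1	M	S_C1	Sy	S_C1	S_C1/S_C1	0
c1	sc1	M	Sx	S_C1	M	S_C1	Sy	S_C1	Sx/Sy	67
c1	sc1	M	Sx	S_C1	M	S_C1	Sy	S_C1	S_C1/Sy	44
c2	sc1_ortho	Rm09	S8	S7	Rm08	S7	S6	S7	S8/S7	0
c2	sc1_ortho	Rm09	S8	S7	Rm08	S7	S6	S7	S7/S7	0
c2	sc1_ortho	Rm09	S8	S7	Rm08	S7	S6	S7	S8/S6	10
c2	sc1_ortho	Rm09	S8	S7	Rm08	S7	S6	S7	S7/S6	16
c3	sc1_ortho	M	Sx	S9	M	S9	Sy	S9	Sx/S9	0
c3	sc1_ortho	M	Sx	S9	M	S9	Sy	S9	S9/S9	0
c3	sc1_ortho	M	Sx	S9	M	S9	Sy	S9	Sx/Sy	26
c3	sc1_ortho	M	Sx	S9	M	S9	Sy	S9	S9/Sy	24
c4	sc1_ortho	M	Sx	S11	M	S11	Sy	S11	Sx/S11	0
c4	sc1_ortho	M	Sx	S11	M	S11	Sy	S11	S11/S11	0
c4	sc1_ortho	M	Sx	S11	M	S11	Sy	S11	Sx/Sy	27
c4	sc1_ortho	M	Sx	S11	M	S11	Sy	S11	S11/Sy	21
c5	sc1_ortho	M	Sx	S13	M	S13	Sy	S13	Sx/S13	0
c5	sc1_ortho	M	Sx	S13	M	S13	Sy	S13	S13/S13	0
c5	sc1_ortho	M	Sx	S13	M	S13	Sy	S13	Sx/Sy	23
c5	sc1_ortho	M	Sx	S13	M	S13	Sy	S13	S13/Sy	27
c6	tf_ob	TF	S21	S_C2	OB	S_C2	S_C1	S_C2	S21/S_C2	0
c6	tf_ob	TF	S21	S_C2	OB	S_C2	S_C1	S_C2	S_C2/S_C2	0
c6	tf_ob	TF	S21	S_C2	OB	S_C2	S_C1	S_C2	S21/S_C1	35
c6	tf_ob	TF	S21	S_C2	OB	S_C2	S_C1	S_C2	S_C2/S_C1	25
c7	sc2_ortho	M	Sx	S6	M	S6	Sy	S6	Sx/S6	0
c7	sc2_ortho	M	Sx	S6	M	S6	Sy	S6	S6/S6	0
c7	sc2_ortho	M	Sx	S6	M	S6	Sy	S6	Sx/Sy	26
c7	sc2_ortho	M	Sx	S6	M	S6	Sy	S6	S6/Sy	23
c8	sc2_ortho	M	Sx	S10	M	S10	Sy	S10	Sx/S10	0
c8	sc2_ortho	M	Sx	S10	M	S10	Sy	S10	S10/S10	0
c8	sc2_ortho	M	Sx	S10	M	S10	Sy	S10	Sx/Sy	30
c8	sc2_ortho	M	Sx	S10	M	S10	Sy	S10	S10/Sy	17
c9	sc2_ortho	Rm32	S13	S12	Rm33	S12	S9	S12	S13/S12	0
c9	sc2_ortho	Rm32	S13	S12	Rm33	S12	S9	S12	S12/S12	0
c9	sc2_ortho	Rm32	S13	S12	Rm33	S12	S9	S12	S13/S9	13
c9	sc2_ortho	Rm32	S13	S12	Rm33	S12	S9	S12	S12/S9	15
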