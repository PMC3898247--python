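area	strand	transcript	excluded
Sequence 1	-	matR::nad1_ex4
Sequence 1	+	ccmC
Sequence 1	-	atp6
Sequence 1	-	cob::rps14::rpl5::nad1_ex5
Sequence 2	+	nad1_ex1
Sequence 2	+	ccmFc_ex1::ccmFc_ex2
Sequence 2	-	nad6::rps4
Sequence 2	+	nad9
Sequence 2	-	tatC(orfx)
Sequence 2	+	ccmB
Sequence 2	-	orf159b::rpl2_ex1::rpl2_ex2
Sequence 2	-	nad7_ex1::nad7_ex2::nad7_ex3::nad7_ex4
Sequence 3	+	rps12
Sequence 3		rrn18	rRNA
Sequence 3		rrn5	rRNA
Sequence 3	-	orf25(atp4)::nad4L
Sequence 3	-	ccmFN::cox1::rps10_ex1::rps10_ex2
Sequence 3	-	nad1_ex3::nad1_ex2::rsp13::atp9
Sequence 3	+	rps19::rps3_ex1::rps3_ex2::rpl16::cox2_ex1::cox2_ex2
Sequence 3	+	nad5_ex4::nad5_ex5
Sequence 3	+	nad4_ex1::nad4_ex2::nad4_ex3::nad4_ex4::nad5_ex1::nad5_ex2
Sequence 3	+	nad2_ex3::nad2_ex4::nad2_ex5
Sequence 3	-	nad5_ex3
Sequence 3	+	atp8::cox3::atp1
Sequence 3	-	nad2_ex2
Repeat 1		rrn26	rRNA
Repeat 1	-	orf197	solitary_orf
Repeat 2	-	nad2_ex1::sdh3
Repeat 3	+	orf265::nad3
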