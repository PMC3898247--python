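orf	genome_start	genome_stop	peak_doc	edit_sites	super	pellet	role	homology
cox2	156352	158494	17900	14	+	+	control
cox2_EDTA			 	 	+	-	control_edta
orf161	48550	49035	<75	-	+	-	background
177	31683	32216	1537	-	+	+	experimental	none found
197	74704	75297	1900	5	+	-	experimental
265/atp8	85475	86272	2481	2	+	+	experimental	full length ATPase subunit 8
129b	100135	100524	386	-	+	-	experimental
175	102481	103008	215	-	-	-	experimental
25/atp4	113853	114449	13360	10	+	+	experimental	full length ATPase subunit 4
222	114996	115664	8288	-	+	+	experimental	none found
239	171890	172609	1194	-	+	-	experimental
216	191161	191811	5943	-	+	+	experimental	fragment of ribosomal protein S1
306	215367	216287	365	-	+	-	experimental
147	221540	221983	6105	-	+	+	experimental	full length ribosomal protein L10
144	229441	229875	311	-	+	-	experimental
118	229726	230082	387	-	+	-	experimental
160	231140	231622	816	-	+	+	experimental
125d	257199	257576	4404	-	+	-	experimental
115	306250	306597	424	-	+	+	experimental	none found
166b	324805	325305	1182	-	+	+	experimental	fragment of cytochrome oxidase
159b/rpl10	360283	360762	8330	4	+	+	experimental	full length ribosomal protein L10
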