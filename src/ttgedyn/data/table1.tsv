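slotu_id	glotu_id	n_samples	pct_samples_printed	n_infants	pct_infants_printed	first_day	last_day	n_score1	n_score2	n_score3	is_nd	remarks
Staphylococcus epidermidis group	Staphylococcus	268	75.7	30	100	3	53	45	67	156	0
Staphylococcus haemolyticus	Staphylococcus	185	52.3	26	86.7	4	51	34	69	82	0
Staphylococcus warneri	Staphylococcus	45	12.7	16	53.3	3	33	10	16	19	0
Staphylococcus hominis	Staphylococcus	13	13.7	6	20	7	45	4	4	5	0	printed sample percentage 13.7% is a typo; 13/354 = 3.7%
Staphylococcus sp.	Staphylococcus	6	1.7	3	10	3	25	2	3	1	0
Staphylococcus cohnii	Staphylococcus	4	1.1	1	3.3	27	33	4	0	0	0
Enterococcus faecalis	Enterococcus	98	27.7	18	60	3	56	13	19	66	0
Enterococcus durans group	Enterococcus	7	2	2	6.7	31	53	1	2	4	0
Clostridium butyricum	Clostridium/Clostridiaceae	40	11.3	12	40	18	53	8	11	21	0
Clostridium difficile	Clostridium/Clostridiaceae	34	9.6	11	36.7	24	56	14	17	3	0
Clostridium neonatale	Clostridium/Clostridiaceae	29	8.2	10	33.3	16	53	12	12	5	0
Clostridium perfringens	Clostridium/Clostridiaceae	23	6.5	9	30	17	50	8	4	11	0
Clostridium sp.	Clostridium/Clostridiaceae	9	2.5	4	13.3	27	42	6	1	2	0
Clostridium tertium	Clostridium/Clostridiaceae	9	2.5	3	10	22	49	3	3	3	0
Clostridium paraputrificum	Clostridium/Clostridiaceae	5	1.4	3	10	15	18	2	2	1	0
Clostridium disporicum group	Clostridium/Clostridiaceae	5	1.4	2	6.7	15	24	2	2	1	0
Clostridium favososporum	Clostridium/Clostridiaceae	5	1.4	1	3.3	31	50	3	1	1	0
Clostridium symbosium group	Clostridium/Clostridiaceae	2	0.6	1	3.3	21	27	0	1	1	0
Clostridium corinoforum	Clostridium/Clostridiaceae	1	0.3	1	3.3	34	34	1	0	0	0
Clostridium glycolicum	Clostridium/Clostridiaceae	1	0.3	1	3.3	50	50	1	0	0	0
Sarcina ventriculi	Sarcina/Clostridiaceae	1	0.3	1	3.3	17	17	0	0	1	0
Escherichia coli	Enterobacteriaceae	22	6.2	8	26.7	6	56	11	0	11	0
Klebsiella oxytoca	Enterobacteriaceae	13	3.7	4	13.3	12	56	4	1	8	0
Enterobacter cloacae	Enterobacteriaceae	5	1.4	1	3.3	38	56	1	0	4	0
Klebsiella pneumoniae	Enterobacteriaceae	3	0.8	2	6.7	39	49	0	0	3	0
Veillonella dispar	Veillonella	31	8.8	6	20	4	56	20	3	8	0
Veillonella parvula	Veillonella	9	2.5	3	10	28	45	1	5	3	0
Veillonella sp.	Veillonella	7	2	2	6.7	19	42	2	2	3	0
Rothia mucilaginosa	Rothia	10	2.8	4	13.3	37	52	3	3	4	0
Aquabacterium commune	Aquabacterium/Burkholderiales	7	2	4	13.3	3	41	5	2	0	0
Aquabacterium citratiphilum	Aquabacterium/Burkholderiales	2	0.6	1	3.3	28	30	1	1	0	0
Burkholderiales ND	Burkholderiales	7	2	1	3.3	16	33	5	1	1	0
Streptococcus salivarius	Streptococcus	10	2.8	2	6.7	31	56	5	5	0	0
Streptococcus thermophilus	Streptococcus	5	1.4	1	3.3	16	28	2	1	2	0
Streptococcus oralis group	Streptococcus	4	1.1	3	10	24	50	2	1	1	0
Streptococcus anginosus	Streptococcus	1	0.3	1	3.3	30	30	0	1	0	0
Streptococcus oralis/parasanguinis	Streptococcus	1	0.3	1	3.3	49	49	1	0	0	0
Streptococcus parasanguinis group	Streptococcus	1	0.3	1	3.3	42	42	0	1	0	0
Streptococcus sanguinis group	Streptococcus	1	0.3	1	3.3	28	28	1	0	0	0
Bacillus cereus group	Bacillus/Bacillaceae	4	1.1	4	13.3	9	56	3	0	1	0
Oceanobacillus sp.	Oceanobacillus/Bacillaceae	3	0.8	1	3.3	18	24	3	0	0	0
Bifidobacterium breve	Bifidobacterium	9	2.5	2	6.7	3	49	3	6	0	0
Bifidobacterium longum	Bifidobacterium	5	1.4	2	6.7	22	50	3	2	0	0
Clostridium innocuum	Erysipelotrichaceae	9	2.5	1	3.3	10	36	3	6	0	0
Propionibacterium sp.	Propionibacterium	3	0.8	1	3.3	18	24	1	0	2	0
Propionibacterium acnes	Propionibacterium	2	0.6	1	3.3	43	45	0	2	0	0
Sneathia sanguinegens	Sneathia	2	0.6	1	3.3	3	4	1	0	1	0
Anaerococcus octavius	Anaerococcus	2	0.6	1	3.3	32	37	0	2	0	0
Corynebacterium tuberculostearicum	Corynebacterium	2	0.6	1	3.3	14	15	0	2	0	0
Pseudomonas sp.	Pseudomonas	1	0.3	1	3.3	37	37	0	1	0	0
ND	ND	93	26.3	24	80	3	56	60	16	17	1	bands at 37 distinct migration distances; not counted among the 50 SLOTUs
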