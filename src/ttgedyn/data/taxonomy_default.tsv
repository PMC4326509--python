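slotu_id	glotu_id	plotu_id
Staphylococcus epidermidis group	Staphylococcus	Bacilli
Staphylococcus haemolyticus	Staphylococcus	Bacilli
Staphylococcus warneri	Staphylococcus	Bacilli
Staphylococcus hominis	Staphylococcus	Bacilli
Staphylococcus sp.	Staphylococcus	Bacilli
Staphylococcus cohnii	Staphylococcus	Bacilli
Enterococcus faecalis	Enterococcus	Bacilli
Enterococcus durans group	Enterococcus	Bacilli
Streptococcus salivarius	Streptococcus	Bacilli
Streptococcus thermophilus	Streptococcus	Bacilli
Streptococcus oralis group	Streptococcus	Bacilli
Streptococcus anginosus	Streptococcus	Bacilli
Streptococcus oralis/parasanguinis	Streptococcus	Bacilli
Streptococcus parasanguinis group	Streptococcus	Bacilli
Streptococcus sanguinis group	Streptococcus	Bacilli
Bacillus cereus group	Bacillus/Bacillaceae	Bacilli
Oceanobacillus sp.	Oceanobacillus/Bacillaceae	Bacilli
Clostridium butyricum	Clostridium/Clostridiaceae	Clostridia
Clostridium difficile	Clostridium/Clostridiaceae	Clostridia
Clostridium neonatale	Clostridium/Clostridiaceae	Clostridia
Clostridium perfringens	Clostridium/Clostridiaceae	Clostridia
Clostridium sp.	Clostridium/Clostridiaceae	Clostridia
Clostridium tertium	Clostridium/Clostridiaceae	Clostridia
Clostridium paraputrificum	Clostridium/Clostridiaceae	Clostridia
Clostridium disporicum group	Clostridium/Clostridiaceae	Clostridia
Clostridium favososporum	Clostridium/Clostridiaceae	Clostridia
Clostridium symbosium group	Clostridium/Clostridiaceae	Clostridia
Clostridium corinoforum	Clostridium/Clostridiaceae	Clostridia
Clostridium glycolicum	Clostridium/Clostridiaceae	Clostridia
Sarcina ventriculi	Sarcina/Clostridiaceae	Clostridia
Clostridium innocuum	Erysipelotrichaceae	Clostridia
Anaerococcus octavius	Anaerococcus	Clostridia
Veillonella dispar	Veillonella	Negativicutes
Veillonella parvula	Veillonella	Negativicutes
Veillonella sp.	Veillonella	Negativicutes
Escherichia coli	Enterobacteriaceae	Proteobacteria
Klebsiella oxytoca	Enterobacteriaceae	Proteobacteria
Klebsiella pneumoniae	Enterobacteriaceae	Proteobacteria
Enterobacter cloacae	Enterobacteriaceae	Proteobacteria
Aquabacterium commune	Aquabacterium/Burkholderiales	Proteobacteria
Aquabacterium citratiphilum	Aquabacterium/Burkholderiales	Proteobacteria
Burkholderiales ND	Burkholderiales	Proteobacteria
Pseudomonas sp.	Pseudomonas	Proteobacteria
Rothia mucilaginosa	Rothia	Actinobacteria
Bifidobacterium breve	Bifidobacterium	Actinobacteria
Bifidobacterium longum	Bifidobacterium	Actinobacteria
Propionibacterium sp.	Propionibacterium	Actinobacteria
Propionibacterium acnes	Propionibacterium	Actinobacteria
Corynebacterium tuberculostearicum	Corynebacterium	Actinobacteria
Sneathia sanguinegens	Sneathia	Fusobacteria
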