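# Synthetic stand-in for a frozen KEGG/HMDB metabolite->enzyme extraction.
# Enzyme symbols follow the UniProt-style short names used in the
# parkinsonism literature; assignments are illustrative, not curated.
metabolite_id	enzyme_protein_id	enzyme_gene_id	role	enzyme_class
Ala	ALDH2	ALDH2	degradation	amino_acid_metabolism
Ala	AL1B1	ALDH1B1	degradation	amino_acid_metabolism
Pro	P5CR1	PYCR1	biosynthesis	amino_acid_metabolism
Pro	P4HA1	P4HA1	degradation	amino_acid_metabolism
Pro	P4HA2	P4HA2	degradation	amino_acid_metabolism
Ile	BCAT1	BCAT1	degradation	amino_acid_metabolism
Ile	BCAT2	BCAT2	degradation	amino_acid_metabolism
Val	BCAT1	BCAT1	degradation	amino_acid_metabolism
Val	BCAT2	BCAT2	degradation	amino_acid_metabolism
Met	S22A6	SLC22A6	degradation	amino_acid_metabolism
C0	CPT1A	CPT1A	biosynthesis	acylcarnitine_metabolism
C0	OCTC	CROT	degradation	acylcarnitine_metabolism
C2	ODPA	PDHA1	biosynthesis	acylcarnitine_metabolism
C2	ODPB	PDHB	biosynthesis	acylcarnitine_metabolism
C2	ACC1	ACACA	degradation	acylcarnitine_metabolism
C3	ODPB	PDHB	degradation	acylcarnitine_metabolism
C4	ACC1	ACACA	biosynthesis	acylcarnitine_metabolism
C5	UD11	UGT1A1	degradation	acylcarnitine_metabolism
C6	OCTC	CROT	biosynthesis	acylcarnitine_metabolism
C8	OCTC	CROT	degradation	acylcarnitine_metabolism
C8	FURIN	FURIN	degradation	acylcarnitine_metabolism
C10	CPT1B	CPT1B	biosynthesis	acylcarnitine_metabolism
C10:1	CPT1B	CPT1B	degradation	acylcarnitine_metabolism
C12	CPT1A	CPT1A	biosynthesis	acylcarnitine_metabolism
C12:1	CPT1C	CPT1C	biosynthesis	acylcarnitine_metabolism
C14	FAS	FASN	biosynthesis	acylcarnitine_metabolism
C14:1	FAS	FASN	degradation	acylcarnitine_metabolism
C16	CPT1A	CPT1A	degradation	acylcarnitine_metabolism
C16	FAS	FASN	biosynthesis	acylcarnitine_metabolism
C16:1	CPT1B	CPT1B	degradation	acylcarnitine_metabolism
C18	CPT1A	CPT1A	biosynthesis	acylcarnitine_metabolism
C18:1	CPT1C	CPT1C	degradation	acylcarnitine_metabolism
C18:1	FURIN	FURIN	biosynthesis	acylcarnitine_metabolism
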