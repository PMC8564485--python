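#version=2021.1
# Default gene catalog for hydrogen sulfide and methane production in the
# human gut microbiome.
#
# Cysteine-degradation genes are partitioned into three tiers by how central
# H2S release is to the enzyme's function: "primary" enzymes degrade cysteine
# to H2S as their main activity; "secondary" enzymes release H2S but also act
# in other pathways (transsulfuration, maltose regulon modulation); "erroneous"
# enzymes have a well-defined non-H2S main function and only incidentally
# produce H2S. Dissimilatory sulfate reduction is marked by the dsrAB operon
# ("dsr" tier), and a 16-gene hydrogenotrophic methanogenesis panel is carried
# in the "methanogenesis" tier for metatranscriptomic calling.
#
# phmm_id values are stable placeholder accessions keyed to the gene symbol;
# replace them with your curated TIGRFAM/HAMAP accessions when wiring real
# profile databases. An empty bit_score_min on a TIGRFAM row falls back to the
# loader's default floor (25 bits) unless overridden.
symbol	tier	phmm_id	phmm_source	bit_score_min	notes
dcyD	primary	PH_dcyD	TIGRFAM		D-cysteine desulfhydrase
yhaM	primary	PH_yhaM	custom		cysteine desulfidase
mgl	primary	PH_mgl	custom		methionine gamma-lyase, degrades cysteine to H2S
sseA	primary	PH_sseA	HAMAP		3-mercaptopyruvate sulfurtransferase
metC	secondary	PH_metC	TIGRFAM		cystathionine beta-lyase, transsulfuration
malY	secondary	PH_malY	HAMAP		bifunctional beta-lyase / maltose regulon modulator
cysK	secondary	PH_cysK	TIGRFAM		O-acetylserine sulfhydrylase A
cysM	secondary	PH_cysM	TIGRFAM		O-acetylserine sulfhydrylase B
mccB	secondary	PH_mccB	custom		cystathionine gamma-lyase homolog
tnaA	erroneous	PH_tnaA	TIGRFAM		tryptophanase, indole production
iscS	erroneous	PH_iscS	TIGRFAM		cysteine desulfurase, Fe-S cluster assembly
mccA	erroneous	PH_mccA	custom		O-acetylserine sulfhydrylase homolog
dsrA	dsr	PH_dsrA	TIGRFAM		dissimilatory sulfite reductase alpha subunit
dsrB	dsr	PH_dsrB	TIGRFAM		dissimilatory sulfite reductase beta subunit
fwdA	methanogenesis	PH_fwdA	custom		formylmethanofuran dehydrogenase subunit A
fwdB	methanogenesis	PH_fwdB	custom		formylmethanofuran dehydrogenase subunit B
ftr	methanogenesis	PH_ftr	custom		formylmethanofuran-H4MPT formyltransferase
mch	methanogenesis	PH_mch	custom		methenyl-H4MPT cyclohydrolase
mtd	methanogenesis	PH_mtd	custom		methylene-H4MPT dehydrogenase
mer	methanogenesis	PH_mer	custom		methylene-H4MPT reductase
mtrA	methanogenesis	PH_mtrA	custom		methyl-H4MPT:CoM methyltransferase subunit A
mtrB	methanogenesis	PH_mtrB	custom		methyl-H4MPT:CoM methyltransferase subunit B
mtrE	methanogenesis	PH_mtrE	custom		methyl-H4MPT:CoM methyltransferase subunit E
mtrH	methanogenesis	PH_mtrH	custom		methyl-H4MPT:CoM methyltransferase subunit H
mcrA	methanogenesis	PH_mcrA	custom		methyl-CoM reductase alpha subunit
mcrB	methanogenesis	PH_mcrB	custom		methyl-CoM reductase beta subunit
mcrG	methanogenesis	PH_mcrG	custom		methyl-CoM reductase gamma subunit
hdrA	methanogenesis	PH_hdrA	custom		heterodisulfide reductase subunit A
hdrB	methanogenesis	PH_hdrB	custom		heterodisulfide reductase subunit B
hdrC	methanogenesis	PH_hdrC	custom		heterodisulfide reductase subunit C
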