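lncrna	mirna	mrna	lnc_dir	mi_dir	mrna_dir
AC011511.5	hsa-miR-520c-5p	GABARAPL2	up	down	up
AC011511.5	hsa-miR-520c-5p	HMOX1	up	down	up
AC011511.5	hsa-miR-520c-5p	NOX4	up	down	up
AC011511.5	hsa-miR-520c-5p	STMN1	up	down	up
AC011511.5	hsa-miR-520c-5p	TXNIP	up	down	up
AC011511.5	hsa-miR-518d-5p	GABARAPL2	up	down	up
AC011511.5	hsa-miR-518d-5p	HMOX1	up	down	up
AC011511.5	hsa-miR-518d-5p	NOX4	up	down	up
AC011511.5	hsa-miR-518d-5p	STMN1	up	down	up
AC011511.5	hsa-miR-518d-5p	TXNIP	up	down	up
AC011511.5	hsa-miR-518f-5p	GABARAPL2	up	down	up
AC011511.5	hsa-miR-518f-5p	HMOX1	up	down	up
AC011511.5	hsa-miR-518f-5p	NOX4	up	down	up
AC011511.5	hsa-miR-518f-5p	STMN1	up	down	up
AC011511.5	hsa-miR-518f-5p	TXNIP	up	down	up
AC011511.5	hsa-miR-665	GABARAPL2	up	down	up
AC011511.5	hsa-miR-665	HMOX1	up	down	up
AC011511.5	hsa-miR-665	NOX4	up	down	up
AC011511.5	hsa-miR-665	STMN1	up	down	up
AC011511.5	hsa-miR-665	TXNIP	up	down	up
AL358072.1	hsa-miR-138-5p	AGPAT3	down	up	down
AL358072.1	hsa-miR-138-5p	HERPUD1	down	up	down
AL358072.1	hsa-miR-138-5p	JDP2	down	up	down
AL358072.1	hsa-miR-138-5p	SLC38A	down	up	down
AL358072.1	hsa-miR-138-5p	SQSTM1	down	up	down
AL358072.1	hsa-miR-138-5p	UBC	down	up	down
AL358072.1	hsa-miR-122-5p	AGPAT3	down	up	down
AL358072.1	hsa-miR-122-5p	HERPUD1	down	up	down
AL358072.1	hsa-miR-122-5p	JDP2	down	up	down
AL358072.1	hsa-miR-122-5p	SLC38A	down	up	down
AL358072.1	hsa-miR-122-5p	SQSTM1	down	up	down
AL358072.1	hsa-miR-122-5p	UBC	down	up	down
C9orf139	hsa-miR-138-5p	AGPAT3	down	up	down
C9orf139	hsa-miR-138-5p	HERPUD1	down	up	down
C9orf139	hsa-miR-138-5p	JDP2	down	up	down
C9orf139	hsa-miR-138-5p	SLC38A	down	up	down
C9orf139	hsa-miR-138-5p	SQSTM1	down	up	down
C9orf139	hsa-miR-138-5p	PROM2	down	up	down
C9orf139	hsa-miR-490-3p	AGPAT3	down	up	down
C9orf139	hsa-miR-490-3p	HERPUD1	down	up	down
C9orf139	hsa-miR-490-3p	JDP2	down	up	down
C9orf139	hsa-miR-490-3p	SLC38A	down	up	down
C9orf139	hsa-miR-490-3p	SQSTM1	down	up	down
C9orf139	hsa-miR-490-3p	PROM2	down	up	down
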