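# Curated CAR T-cell / tumor-cell interaction logic model (CD3zeta + CD28 CAR).
# 59 nodes; default propensities pa=0.5, pd=0.05 on every node.
# Curation notes are carried as @meta entries below.
@model cart_table1
@meta curation.LCK = printed LCK rule had two unclosed parentheses; minimally balanced preserving the token sequence
@meta curation.PERGRZB = node printed as PERGRZM but referenced as PERGRZB; canonical name PERGRZB (PERGRZM accepted as alias)
@meta curation.CINHIB = node printed as CINHI; canonicalized to CINHIB to match the readout name p_cinhib
@meta curation.CFUNC = printed rule referenced undefined symbol CDSYF; dropped, leaving AP1 & NFAT & MTORC1

# Inputs: ligand expression set by scenario, not by network dynamics.
TAex = 0, role=input, compartment=interface
IL2ex = 0, role=input, compartment=interface
PDL1L2ex = 0, role=input, compartment=interface
CD8086ex = 0, role=input, compartment=interface

# Tumor antigen and immune synapse
TA = TAex, compartment=tumor
IS = !CASP3CASP7, compartment=interface

# CAR engagement and proximal kinases
SCFV = IS & TA
CD28 = SCFV & LCK
CD3zeta = LCK & CD28
LCK = !LCK & ((!SHP1 | (SHP1 & ERK)) & ((!SHP2 | (SHP2 & ERK))))
ZAP70 = CD3zeta & LCK & !(SHP1 | SHP2)

# IL2 cytokine signaling
IL2 = IL2ex, compartment=interface
IL2R = IL2
JAK13 = IL2R

# Inhibitory receptor engagement
PDL1L2 = PDL1L2ex, compartment=interface
PD1ex = PDCD1ge
PD1 = IS & PDL1L2
CD8086 = CD8086ex, compartment=interface
CTLA4ex = Calcium
CTLA4 = IS & CD8086 & CTLA4ex
SHP2 = PD1 | CTLA4
SHP1 = (PD1 & !SHP2) | (LCK & !ERK)

# Signal transduction into MAPK / PKC / calcium pathways
LAT = ZAP70
SLP76 = ZAP70 | LAT
PLCgamma1 = SLP76
DAG = PLCgamma1
IP3 = PLCgamma1
WASPCDC42 = SLP76
P38 = ZAP70
PKCtheta = (DAG | PDPK1) & !(SHP1 | SHP2)
PI3K = CD28 | CTLA4
PDPK1 = PI3K
AKT = PI3K & PDPK1
MTORC1 = AKT
RASGRP = DAG
GRB2SOS = LAT | JAK13 | CD28
ERK = (RASGRP | GRB2SOS) & !(SHP1 | SHP2)
Calcium = IP3
Calmodulin = Calcium
Calcineurin = Calcium & Calmodulin

# Transcription factors and gene expression
CFOS = ERK | CREB
CJUN = PKCtheta | WASPCDC42
AP1 = CFOS & CJUN & !dNFAT
BATF = PD1
NFKB = PKCtheta
NFAT = Calcineurin | P38
dNFAT = (NFAT & !AP1) | (NFAT & !STAT5)
CREB = P38 | Calmodulin
STAT5 = IL2R & JAK13
IL2ge = AP1 & NFKB & NFAT
PDCD1ge = (AP1 & NFAT) | (STAT5 & NFAT)

# Cytotoxic machinery and tumor apoptosis
CYTOGRAN = WASPCDC42 & PKCtheta & Calcium & PI3K
FASL = CYTOGRAN
PERGRZB = CYTOGRAN
FAS = FASL, compartment=tumor
CASP3CASP7 = FASL | PERGRZB, compartment=tumor

# Readouts: signaling signatures
CFUNC = AP1 & NFAT & MTORC1, role=readout
CINHIB = dNFAT | BATF, role=readout
TAPOP = CASP3CASP7, role=readout, compartment=tumor
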