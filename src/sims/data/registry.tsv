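node_name	genes	drugs
HER	EGF;TGFA;AREG;EREG;HUGE;BTC;NRG1;NRG2;NRG4;EGFR;ERBB2;ERBB3;ERBB4	Afatinib;Dacomitinib (pan-HER inhibitor)
CDK4,6	CDK4;CDK6;CCND1;CCND2;CCND3;COKN2A;CDKN2B;CCNE1;CCNE2;CCNE3;RB1	Palbociclib (CDK4,6 inhibitor)
PLK/AURK	PLK1;AURKA;BORA;ILK;KIF11	Aurora A kinase inhibitor
Angiogenes	VEGFA;VEGFB;VEGFC;VEGFD;VEGFR1;VEGFR2;VEGFR3;PDGFA;PDGFB;PDGFRA;PDGFRB;KIT	Axitinib;Motesanib
Angiopoietins	THBS1;TGFBI;ANGPT1;ANGPT2;ANGPTL1;ANGPT4;TIE1;TEK
Immune modulator	PDL1;PDCD1LG2;PDCD1;CTLA4;LAG3	Ipilimumab (CTLA4);Tremelimumab (CTLA4);Nivolumab (PD1);AMP514 (PD1);Pidilizumab (PD-1);MEDI4736 (PD-L1);PF-05082566 (4-1BB)
PI3K	PIK3CA;PIK3CB;PIK3CD;PIK3CG;PIK3C2B;PRKCB;PRKCA;PIK3R1;PIK3R2;PIK3R3	PF-384 (PI3K/mTOR inhibitor);AZD8186 (PI3Kb);PI3Kalpha inhibitor
MET	HGF;MET;AXL;MST1R	Crizotinib;Cabozantinib;Volitinib (cMet)
MEK	MAP2K1;MAP2K2;MAP2K3;MAP2K4;MAP3K1;MAP3K2;MAP3K3;MAP3K4	Trametinib;Selumetinib (MEK)
ERK	MAPK3;MAPK1;KSR1;MAPK11
Antiapoptosis	BCL2;BCLXL;BIRC5;XIAP;BAK;TP53	ABT-199 (BCL-2);MK-1775 (Wee-1 inhibitor, p53)
FGF	FGF1;FGF2;FGF3;FGF4;FGF5;FGF6;FGF7;FGF8;FGF9;FGF10;FGF11;FGF12;FGF13;FGF14;FGF15;FGF16;FGF17;FGF18;FGFR1;FGFR2;FGFR3;FGFR4	Lenvatinib;Lucitanib;AZD4547 (FGFR1, 2, 3)
mTOR	MTOR;AKT1;AKT2;PTEN;TSC1;TSC2;STK11;PIM1;PIM2;PIM3	Everolimus;Temsirolimus;PF-384 (PI3K/mTOR inhibitor);AZD2014 (TOR kinase);AZD5363 (AKT1, 2, 3);AZD1208 (PIM1, 2);TORC1/TORC2 inhibitor
Ras/Raf	KRAS;NRAS;HRAS;RAF1;BRAF;CRAF	Trametinib;Vemurafenib;Dabrafenib;Pan-RAF inhibitor
Telomerase	TERT;TERC;TEPI;HSP9OAA1;DKC1;PTGES3
IGF	IGF1;IGF2;IGF1R;IGF2R;INSR;IRS1;PKM	Cixutumumab;MEDI-573 (IGF)
Wnt	CDH1;CTNNA1;CTNNB1;WNT1;FZD1;WNT5A;WNT5B;FZDS;WIF1;DKK1	PRI-274
PARP	PARP1;BRCA1;XRCC1;RAD54L;RAD54B;ATM;ATR;CHEK1;CHEK2;WEE1	Olaparib (PARP);AZD1775 (Wee1);AZD6738 (ATR)
HDAC	HDAC1;HDAC2;HDAC3;HDAC4;HDACS	Vorinostat
JAK-STAT	JAK1;JAK2;STAT1;STAT2;STAT3;SOCS1	Ruxolitinib;AZD9150
Hedgehog	SHH;PTCH1;SMO;STK36;PRKACA;SUFU	Vismodegib
NOTCH	NOTCH1;ADAM17;PSEN1;NCSTN;JAG1;SRRT;APH1A	LY3039478
DNA Repair	ERCC1;FTAD52;XRCC4;RAD51;BRCA1;NEDD8;NAE1	NEDD8-activating enzyme inhibitor
Others	RET;ALK;ROS1;UB1	Crizotinib;Ceritinib;Sorafenib;Cabozantinib
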