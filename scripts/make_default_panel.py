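"""One-off generator for the bundled synthetic default panel YAML.

The real 416-gene commercial panel is proprietary; this reconstruction keeps
the genes that matter for the analysis (drivers, MMR/POL, MSI target loci,
pathway membership) and pads to 416 with clearly synthetic filler symbols.
"""
import yaml

REAL_GENES = """
TP53 APC KRAS NRAS HRAS BRAF RAF1 EGFR ERBB2 ERBB3 ERBB4 MET ALK ROS1 RET KIT
PDGFRA PDGFRB FGFR1 FGFR2 FGFR3 FGFR4 NF1 PTPN11 SOS1 MAP2K1 MAP2K2 MAPK1
RASA1 CBL JAK1 JAK2 JAK3 FLT3 FLT4 NTRK1 NTRK2 NTRK3 IGF1R KDR
CTNNB1 RNF43 AXIN1 AXIN2 AMER1 TCF7L2 LRP5 LRP6 ZNRF3 GSK3B DKK1 WIF1 CHD4
LZTR1 SOX9 TLE3
PIK3CA PIK3CB PIK3R1 PIK3R2 PTEN AKT1 AKT2 AKT3 MTOR TSC1 TSC2 RICTOR STK11
INPP4B PDK1 RPTOR
MDM2 MDM4 ATM ATR CHEK1 CHEK2 TP53BP1 RPS6KA3
RB1 CDKN2A CDKN2B CDKN1A CDKN1B CCND1 CCND2 CCND3 CCNE1 CDK4 CDK6 CDK12 E2F1
BUB1B AURKA AURKB PLK1 WEE1 TTK
MYC MYCN MYCL MAX MXI1 MGA MLST8
NOTCH1 NOTCH2 NOTCH3 NOTCH4 FBXW7 CREBBP EP300 SPEN KAT2B MAML1
NF2 LATS1 LATS2 STK3 STK4 YAP1 TAOK1 SAV1 FAT1 FAT4
TGFBR1 TGFBR2 SMAD2 SMAD3 SMAD4 ACVR2A ACVR1B BMPR1A ACVR1
MLH1 MSH2 MSH6 MLH3 PMS1 PMS2 MSH3 POLE POLD1 POLH EPCAM
ARID1A ARID1B ARID2 SMARCA4 SMARCB1 SMARCA2 PBRM1 KMT2A KMT2B KMT2C KMT2D
KDM6A KDM5C SETD2 EZH2 DNMT3A TET2 ASXL1 IDH1 IDH2 CTCF BCOR
BRCA1 BRCA2 PALB2 BAP1 RAD50 RAD51 RAD51B RAD51C RAD51D BARD1 BRIP1 MRE11
NBN BLM WRN NAT1 ERCC2 ERCC3 ERCC4 ERCC5 XPC MUTYH NTHL1 FANCA FANCC FANCD2
FANCE FANCF FANCG ATRX RECQL4
GNAS GNAQ GNA11 GNA13 VHL TERT KEAP1 NFE2L2 CUL3 STAG2 RAD21 SPOP MED12
DICER1 DROSHA PPP2R1A PPP6C SF3B1 SRSF2 U2AF1 ZRSR2 PTCH1 SMO GLI1 SUFU
HNF1A FOXL2 FOXA1 GATA3 GATA4 GATA6 RUNX1 NPM1 CDH1 CDH11 ESR1 AR CIC FUBP1
DAXX MEN1 RNF213 KIF1B AXL EPHA2 EPHB1 ERRFI1 IRS2 MAP3K1 MAP3K13 MAPK3
PIK3C2B PIK3CG PREX2 RHEB RHOA RIT1 SDHA SDHB SDHC SDHD SDHAF2 TSHR SMC1A
SMC3 SETBP1 SETD1A SUZ12 EED TENT5C WHSC1 WHSC1L1 HIST1H3B H3F3A CARD11
CASP8 CBFB CCNQ CD274 PDCD1LG2 CD79A CD79B CDC73 CEBPA CRKL CRLF2 CSF1R
CSF3R CTLA4 CTNNA1 CYLD DDR2 DIS3 DNAJB1 DOT1L EGFL7 EIF1AX EIF4A2 EPHA3
EPHA5 EPHB4 ERF ERG ETV1 ETV4 ETV5 ETV6 EWSR1 FANCL FAS FGF19 FGF3 FGF4
FH FLCN FLI1 FOXO1 FOXP1 FYN GREM1 GRIN2A GSK3A HGF HNRNPK HOXB13 ID3
IKBKE IKZF1 IL7R INHBA INSR IRF2 IRF4 KBTBD4 KEL KLF4 KLHL6 LMO1 LYN
MALT1 MAP2K4 MCL1 MDC1 MEF2B MITF MST1R MYD88 NCOA3 NCOR1 NKX2-1 NKX3-1
NSD1 NTHL2 NUP93 PAK1 PAK3 PARP1 PAX5 PBX1 PDCD1 PGR PHOX2B PIM1 PLCG2
PMS2L1 PPARG PRDM1 PRKAR1A PRKCI PRKDC PTPRD PTPRS PTPRT RAC1 RAD52 RAD54L
REL RHOB RPS6KB1 RXRA RYBP SH2B3 SHQ1 SLX4 SMARCD1 SMYD3 SOCS1 SOX17 SOX2
SPTA1 SRC STAT3 STAT5A STAT5B SYK TAF1 TBX3 TCF3 TERC TMEM127 TMPRSS2
TNFAIP3 TNFRSF14 TOP1 TP63 TRAF2 TRAF7 VEGFA XIAP XPO1 ZBTB2 ZFHX3 ZNF217
""".split()

seen = set()
genes = []
for g in REAL_GENES:
    if g not in seen:
        seen.add(g)
        genes.append(g)

i = 1
while len(genes) < 416:
    name = f"SYNG{i:03d}"  # synthetic filler symbol
    if name not in seen:
        genes.append(name)
        seen.add(name)
    i += 1
genes = genes[:416]

PATHWAYS = {
    "RTK_RAS": "KRAS NRAS HRAS BRAF RAF1 EGFR ERBB2 ERBB3 ERBB4 MET ALK ROS1 "
               "RET KIT PDGFRA PDGFRB FGFR1 FGFR2 FGFR3 FGFR4 NF1 PTPN11 SOS1 "
               "MAP2K1 MAP2K2 MAPK1 RASA1 CBL JAK2 FLT3 NTRK1 NTRK2 NTRK3".split(),
    "Wnt": "APC CTNNB1 RNF43 AXIN1 AXIN2 AMER1 TCF7L2 LRP5 LRP6 ZNRF3 GSK3B "
           "DKK1 WIF1 CHD4 LZTR1".split(),
    "PI3K": "PIK3CA PIK3CB PIK3R1 PIK3R2 PTEN AKT1 AKT2 AKT3 MTOR TSC1 TSC2 "
            "RICTOR STK11 INPP4B".split(),
    "p53": "TP53 MDM2 MDM4 ATM ATR CHEK1 CHEK2 TP53BP1".split(),
    "Cell_Cycle": "RB1 CDKN2A CDKN2B CDKN1A CDKN1B CCND1 CCND2 CCND3 CCNE1 "
                  "CDK4 CDK6 E2F1 BUB1B".split(),
    "Myc": "MYC MYCN MYCL MAX MXI1 MGA".split(),
    "Notch": "NOTCH1 NOTCH2 NOTCH3 NOTCH4 FBXW7 CREBBP EP300 SPEN KAT2B".split(),
    "Hippo": "NF2 LATS1 LATS2 STK3 STK4 YAP1 TAOK1 SAV1 FAT1".split(),
    "TGF_Beta": "TGFBR1 TGFBR2 SMAD2 SMAD3 SMAD4 ACVR2A ACVR1B".split(),
}
for pw, members in PATHWAYS.items():
    missing = set(members) - seen
    assert not missing, (pw, missing)

# simplified autosome model: decreasing lengths, sums to ~3.0 Gb
chrom_lengths = {f"chr{i}": 250_000_000 - (i - 1) * 9_000_000 for i in range(1, 23)}

# block-assign genes to chromosomes; fixed-size slots, no overlap within chrom
n_chrom = 22
per_chrom = -(-len(genes) // n_chrom)
gene_intervals = {}
for idx, g in enumerate(genes):
    ci = idx // per_chrom + 1
    slot = idx % per_chrom
    chrom = f"chr{ci}"
    start = 5_000_000 + slot * 2_500_000
    gene_intervals[g] = [chrom, start, start + 100_000]

# co-located pairs the analysis cares about (concurrent CNV behaviour)
gene_intervals["WRN"] = ["chr8", 30_000_000, 30_140_000]
gene_intervals["NAT1"] = ["chr8", 30_160_000, 30_280_000]
gene_intervals["CDKN2A"] = ["chr9", 21_960_000, 21_990_000]
gene_intervals["CDKN2B"] = ["chr9", 22_000_000, 22_030_000]
for g, (c, s, e) in gene_intervals.items():
    assert e <= chrom_lengths[c], g

units = "AT"
msi_loci = []
for k in range(52):
    chrom = f"chr{(k % 22) + 1}"
    msi_loci.append({
        "locus_id": f"MSI_{k + 1:02d}",
        "chrom": chrom,
        "start": 10_000_000 + (k // 22) * 7_000_000 + (k % 22) * 137_000,
        "repeat_unit": units[k % 2],
        "reference_repeat_len": 15 + (k % 13),  # 15..27 bp
    })

cfg = {
    "name": "gi416_synthetic",
    "description": ("Synthetic default configuration of a 416-gene GI-cancer "
                    "targeted panel (1.2 Mb coding target): gene list, nine "
                    "signaling-pathway map, MMR/POL gene sets, gene intervals "
                    "on a simplified 22-autosome model, and 52 mononucleotide "
                    "microsatellite loci."),
    "target_size_mb": 1.2,
    "genes": genes,
    "pathways": PATHWAYS,
    "mmr_genes": ["MLH1", "MSH2", "MSH6", "MLH3", "PMS1", "PMS2"],
    "pol_genes": ["POLE", "POLD1", "POLH"],
    "chrom_lengths": chrom_lengths,
    "gene_intervals": gene_intervals,
    "msi_loci": msi_loci,
}

out = "src/gilandscape/data/default_panel_synthetic.yaml"
import os
os.makedirs(os.path.dirname(out), exist_ok=True)
with open(out, "w") as fh:
    fh.write("# Synthetic default panel configuration (reconstructed stand-in;\n"
             "# gene coordinates, filler SYNG* symbols and MSI loci are simulated).\n")
    yaml.safe_dump(cfg, fh, sort_keys=False, default_flow_style=None, width=100)
print(len(genes), "genes;", len(msi_loci), "loci")
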