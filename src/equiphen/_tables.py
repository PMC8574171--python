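"""Published per-cell-type gene lists used as packaged fixtures.

Two tables of murine prefrontal-cortex gene symbols, each partitioned into
five expression classes over the two neuron groups (Pyr = pyramidal cells,
FS = fast-spiking interneurons):

* ``TABLE1`` — 100 antimicrobial/immunomodulatory peptide (AMP) genes
  detected in the sequenced neurons (34 even, 6 Pyr-enriched, 9 FS-enriched,
  40 Pyr-specific, 11 FS-specific).
* ``TABLE2`` — 122 immune-cell-process protein genes (59 even, 15
  Pyr-enriched, 11 FS-enriched, 28 Pyr-specific, 9 FS-specific).

``SYNTHETIC_AMP_LIST_186`` is a synthetic stand-in for the 186-entry AMP
reference list of the original analysis (which lives in an external
supplement): the 100 published detected AMP symbols above plus 86
clearly-synthetic placeholder symbols standing in for the undetected
entries, so that list size and coverage arithmetic (100/186) are preserved.
"""

from __future__ import annotations

TABLE1: dict[str, list[str]] = {
    "even": [
        "Ang2", "App", "Atp5f1", "B2m", "Calca", "Camp", "Ccl25", "Ccl27a",
        "Ccl28", "Chga", "Clu", "Cxcl11", "Defb35", "Dmbt1", "Fau", "Fga",
        "Furin", "Gapdh", "H2aj", "Hist1h2bc", "Hmgn2", "Hrnr", "Ifih1",
        "Iqgap2", "Isg20", "Lgals3", "Pglyrp4", "Pigr", "Ppbp", "Retn",
        "Sp1", "Vgf", "Vip", "Wfdc12",
    ],
    "enriched_pyr": ["Cxcl12", "Dlc1", "Lyz2", "Romo1", "Snca", "Tor2a"],
    "enriched_fs": [
        "Apobec3", "Ccl4", "Cxcl1", "Cxcl2", "Cxcl10", "Defb30", "Mx1",
        "Npy", "Tac1",
    ],
    "specific_pyr": [
        "Adm", "Ang4", "Bpifa1", "Bpifa2", "Bpifb4", "Bst2", "Ccl17",
        "Cxcl3", "Cxcl9", "Cxcl13", "Cxcl14", "Defb1", "Defb3", "Defb5",
        "Defb11", "Defb13", "Defb15", "Defb28", "Defb29", "Flg2", "Gbp1",
        "Gpr15", "Hp", "Kng1", "Lyz1", "Nts", "Pglyrp3", "Pla2g2a", "Pomc",
        "Prf1", "Prg2", "Rarres2", "Rnase6", "S100a7a", "S100a9",
        "Serpina1c", "Serpina1e", "Serpind1", "Spag11b", "Xcl1",
    ],
    "specific_fs": [
        "Ccl22", "Ccl24", "Defb2", "F2", "Galp", "Gbp2", "Ifnl3", "Klk5",
        "Leap2", "Ltf", "Zg16",
    ],
}

TABLE2: dict[str, list[str]] = {
    "even": [
        "Aicda", "B2m", "Bcl10", "Calr", "Canx", "Card11", "Cd19", "Cd247",
        "Cd28", "Cd74", "Cd79a", "Cd81", "Creb1", "Ctss", "Fcer1g", "Grb2",
        "Ifng", "Il2", "Il4ra", "Il7", "Il7r", "Itpr1", "Jak1", "Jak2",
        "Lck", "Lgmn", "Lyn", "Malt1", "Map2k1", "Map2k2", "Map2k3",
        "Map2k7", "Map3k1", "Map3k14", "Map3k7", "Mapk1", "Mapk3", "Mapk9",
        "Nfatc2", "Pak1", "Pdia3", "Pdpk1", "Plcg1", "Plcg2", "Prkcb",
        "Ptk2b", "Raf1", "Rag1", "Rasgrp3", "Tap1", "Ticam1", "Ticam2",
        "Tnfrsf13b", "Tnfrsf13c", "Tnfrsf17", "Traf2", "Traf3", "Tyk2",
        "Vav1",
    ],
    "enriched_pyr": [
        "Blnk", "Ccr7", "Fcgr2b", "Itgal", "Jun", "Lat", "Map3k8", "Mapk14",
        "Rac1", "Rag2", "Sos1", "Stat1", "Stat4", "Tapbp", "Tpp2",
    ],
    "enriched_fs": [
        "Akt1", "Cd3d", "Cr2", "Fasl", "Fos", "Il12b", "Nfkbia", "Stat5a",
        "Syk", "Tap2", "Traf6",
    ],
    "specific_pyr": [
        "Btk", "C3", "Cd14", "Cd22", "Cd72", "Cd79b", "Cd86", "Gzma",
        "Gzmb", "H2-Dma", "H2-Oa", "H2-Ob", "Ifi30", "Il12rb2", "Il2ra",
        "Il4", "Inpp5d", "Jak3", "Lta", "Pax5", "Prf1", "Prkcq", "Ptpn6",
        "Stat6", "Tbx21", "Tlr4", "Tnfsf13b", "Zap70",
    ],
    "specific_fs": [
        "Cd3e", "Cd3g", "Cd4", "Cd40", "Cd40lg", "Cd80", "Cd8a", "Il2rb",
        "Il5",
    ],
}

# Synthetic stand-in for the external 186-entry AMP reference list: the 100
# published detected symbols plus 86 synthetic placeholders for the
# undetected entries.
SYNTHETIC_AMP_LIST_186: list[str] = [
    s for column in TABLE1.values() for s in column
] + [f"SynthAmp{i:03d}" for i in range(1, 87)]
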