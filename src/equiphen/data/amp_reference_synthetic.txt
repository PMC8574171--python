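# Synthetic stand-in for the 186-entry antimicrobial/immunomodulatory
# peptide (AMP) reference list: 100 published detected symbols plus 86
# synthetic placeholder entries (SynthAmp...).
Ang2
App
Atp5f1
B2m
Calca
Camp
Ccl25
Ccl27a
Ccl28
Chga
Clu
Cxcl11
Defb35
Dmbt1
Fau
Fga
Furin
Gapdh
H2aj
Hist1h2bc
Hmgn2
Hrnr
Ifih1
Iqgap2
Isg20
Lgals3
Pglyrp4
Pigr
Ppbp
Retn
Sp1
Vgf
Vip
Wfdc12
Cxcl12
Dlc1
Lyz2
Romo1
Snca
Tor2a
Apobec3
Ccl4
Cxcl1
Cxcl2
Cxcl10
Defb30
Mx1
Npy
Tac1
Adm
Ang4
Bpifa1
Bpifa2
Bpifb4
Bst2
Ccl17
Cxcl3
Cxcl9
Cxcl13
Cxcl14
Defb1
Defb3
Defb5
Defb11
Defb13
Defb15
Defb28
Defb29
Flg2
Gbp1
Gpr15
Hp
Kng1
Lyz1
Nts
Pglyrp3
Pla2g2a
Pomc
Prf1
Prg2
Rarres2
Rnase6
S100a7a
S100a9
Serpina1c
Serpina1e
Serpind1
Spag11b
Xcl1
Ccl22
Ccl24
Defb2
F2
Galp
Gbp2
Ifnl3
Klk5
Leap2
Ltf
Zg16
SynthAmp001
SynthAmp002
SynthAmp003
SynthAmp004
SynthAmp005
SynthAmp006
SynthAmp007
SynthAmp008
SynthAmp009
SynthAmp010
SynthAmp011
SynthAmp012
SynthAmp013
SynthAmp014
SynthAmp015
SynthAmp016
SynthAmp017
SynthAmp018
SynthAmp019
SynthAmp020
SynthAmp021
SynthAmp022
SynthAmp023
SynthAmp024
SynthAmp025
SynthAmp026
SynthAmp027
SynthAmp028
SynthAmp029
SynthAmp030
SynthAmp031
SynthAmp032
SynthAmp033
SynthAmp034
SynthAmp035
SynthAmp036
SynthAmp037
SynthAmp038
SynthAmp039
SynthAmp040
SynthAmp041
SynthAmp042
SynthAmp043
SynthAmp044
SynthAmp045
SynthAmp046
SynthAmp047
SynthAmp048
SynthAmp049
SynthAmp050
SynthAmp051
SynthAmp052
SynthAmp053
SynthAmp054
SynthAmp055
SynthAmp056
SynthAmp057
SynthAmp058
SynthAmp059
SynthAmp060
SynthAmp061
SynthAmp062
SynthAmp063
SynthAmp064
SynthAmp065
SynthAmp066
SynthAmp067
SynthAmp068
SynthAmp069
SynthAmp070
SynthAmp071
SynthAmp072
SynthAmp073
SynthAmp074
SynthAmp075
SynthAmp076
SynthAmp077
SynthAmp078
SynthAmp079
SynthAmp080
SynthAmp081
SynthAmp082
SynthAmp083
SynthAmp084
SynthAmp085
SynthAmp086
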