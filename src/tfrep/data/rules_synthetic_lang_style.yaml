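# Synthetic reconstruction of a plant TF/TAP mandatory/forbidden rule
# system (Lang et al.-style shape: 111 families, 134 mandatory + 89
# forbidden rules, with database synonyms). The real rule file is not
# public; this stand-in is swappable config with the same structure.
provenance: synthetic-lang-style-reconstruction
families:
  "C2H2":
    mandatory: ["zf-C2H2"]
    forbidden: ["AP2"]
  "PcG_FIE":
    mandatory: ["WD40"]
    forbidden: ["bZIP_1"]
  "MYB-HB-like":
    mandatory: ["Myb_DNA-binding"]
    forbidden: ["PHD"]
  "bHLH":
    mandatory: ["HLH"]
    forbidden: ["Auxin_resp"]
  "CCHC(Zn)":
    mandatory: ["PFX001"]
    forbidden: ["AUX_IAA"]
  "NAC":
    mandatory: ["NAM"]
    forbidden: ["WRC"]
  "WRKY":
    mandatory: ["WRKY"]
    forbidden: ["SRF-TF"]
  "AP2-EREBP":
    mandatory: ["AP2"]
    forbidden: ["YABBY"]
  "bZIP":
    mandatory: ["bZIP_1"]
    forbidden: ["NF-YB"]
  "PHD":
    mandatory: ["PHD"]
    forbidden: ["NF-YC"]
  "ARF":
    mandatory: ["Auxin_resp"]
    forbidden: ["B3"]
  "Aux/IAA":
    mandatory: ["AUX_IAA"]
    forbidden: ["tify"]
  "GRF":
    mandatory: ["WRC"]
    forbidden: ["PFX002"]
  "MADS":
    mandatory: ["SRF-TF"]
    forbidden: ["mTERF"]
  "C2C2-YABBY":
    mandatory: ["YABBY"]
    forbidden: ["Tub"]
  "CCAAT-HAP3":
    mandatory: ["NF-YB"]
    forbidden: ["PFX003"]
  "CCAAT-HAP5":
    mandatory: ["NF-YC"]
    forbidden: ["PFX004"]
  "B3":
    mandatory: ["B3", "B3_C"]
    forbidden: ["PFX005"]
  "tify":
    mandatory: ["tify"]
    forbidden: ["PFX006"]
  "BES/BZR":
    mandatory: ["PFX002", "PFX002_C"]
    forbidden: ["PFX007"]
  "mTERF":
    mandatory: ["mTERF"]
    forbidden: ["PFX008"]
  "TUBBY":
    mandatory: ["Tub", "Tub_C"]
    forbidden: ["PFX009"]
  "MYB-related":
    mandatory: ["PFX003"]
    forbidden: ["PFX010"]
  "NF-X1":
    mandatory: ["PFX004", "PFX004_C"]
    forbidden: ["PFX011"]
  "SOH1":
    mandatory: ["PFX005"]
    forbidden: ["PFX012"]
  "RF-X":
    mandatory: ["PFX006", "PFX006_C"]
    forbidden: ["PFX013"]
  "zn-clus":
    mandatory: ["PFX007"]
    forbidden: ["PFX014"]
  "JmjC-ARID":
    mandatory: ["PFX008", "PFX008_C"]
    forbidden: ["PFX015"]
  "TRAF":
    mandatory: ["PFX009"]
    forbidden: ["PFX016"]
  "Dicer":
    mandatory: ["PFX010", "PFX010_C"]
    forbidden: ["PFX017"]
  "Runt":
    mandatory: ["PFX011"]
    forbidden: ["PFX018"]
  "TEA":
    mandatory: ["PFX012", "PFX012_C"]
    forbidden: ["EIN3"]
  "C2C2-GATA":
    mandatory: ["PFX013"]
    forbidden: ["PFX019"]
  "C2C2-Dof":
    mandatory: ["PFX014", "PFX014_C"]
    forbidden: ["PFX020"]
  "C2C2-CO-like":
    mandatory: ["PFX015"]
    forbidden: ["GRAS"]
  "C3H":
    mandatory: ["PFX016", "PFX016_C"]
    forbidden: ["PFX021"]
  "CPP":
    mandatory: ["PFX017"]
    forbidden: ["HSF_DNA-bind"]
  "E2F-DP":
    mandatory: ["PFX018", "PFX018_C"]
    forbidden: ["PFX022"]
  "EIL":
    mandatory: ["EIN3"]
    forbidden: ["PFX023"]
  "FHA":
    mandatory: ["PFX019", "PFX019_C"]
    forbidden: ["PFX024"]
  "GeBP":
    mandatory: ["PFX020"]
    forbidden: ["PFX025"]
  "GRAS":
    mandatory: ["GRAS", "GRAS_C"]
    forbidden: ["PFX026"]
  "HB":
    mandatory: ["PFX021"]
    forbidden: ["PFX027"]
  "HSF":
    mandatory: ["HSF_DNA-bind", "HSF_DNA-bind_C"]
    forbidden: ["PFX028"]
  "LFY":
    mandatory: ["PFX022"]
    forbidden: ["PFX029"]
  "LIM":
    mandatory: ["PFX023", "PFX023_C"]
    forbidden: ["PFX030"]
  "LOB":
    mandatory: ["PFX024"]
    forbidden: ["SBP"]
  "NZZ":
    mandatory: ["PFX025", "PFX025_C"]
    forbidden: ["PFX031"]
  "OFP":
    mandatory: ["PFX026"]
    forbidden: ["TCP"]
  "PLATZ":
    mandatory: ["PFX027", "PFX027_C"]
    forbidden: ["PFX032"]
  "Pseudo-ARR-B":
    mandatory: ["PFX028"]
    forbidden: ["PFX033"]
  "S1Fa-like":
    mandatory: ["PFX029", "PFX029_C"]
    forbidden: ["PFX034"]
  "SAP":
    mandatory: ["PFX030"]
    forbidden: ["PFX035"]
  "SBP":
    mandatory: ["SBP", "SBP_C"]
    forbidden: ["PFX036"]
  "SRS":
    mandatory: ["PFX031"]
    forbidden: ["PFX037"]
  "TCP":
    mandatory: ["TCP", "TCP_C"]
    forbidden: ["PFX038"]
  "Trihelix":
    mandatory: ["PFX032"]
    forbidden: ["PFX039"]
  "ULT":
    mandatory: ["PFX033", "PFX033_C"]
    forbidden: ["PFX040"]
  "VOZ":
    mandatory: ["PFX034"]
    forbidden: ["PFX041"]
  "Whirly":
    mandatory: ["PFX035", "PFX035_C"]
    forbidden: ["PFX042"]
  "zf-HD":
    mandatory: ["PFX036"]
    forbidden: ["PFX043"]
  "Alfin-like":
    mandatory: ["PFX037", "PFX037_C"]
    forbidden: ["PFX044"]
  "ARID":
    mandatory: ["PFX038"]
    forbidden: ["PFX045"]
  "AUX/ARF-related":
    mandatory: ["PFX039"]
    forbidden: ["PFX046"]
  "BBR/BPC":
    mandatory: ["PFX040"]
    forbidden: ["PFX047"]
  "BSD":
    mandatory: ["PFX041"]
    forbidden: ["PFX048"]
  "Coactivator-p15":
    mandatory: ["PFX042"]
    forbidden: ["PFX049"]
  "DDT":
    mandatory: ["PFX043"]
    forbidden: ["PFX050"]
  "GNAT":
    mandatory: ["PFX044"]
    forbidden: ["PFX051"]
  "HMG":
    mandatory: ["PFX045"]
    forbidden: ["PFX052"]
  "Jumonji":
    mandatory: ["PFX046"]
    forbidden: ["PFX053"]
  "LUG":
    mandatory: ["PFX047"]
    forbidden: ["PFX054"]
  "MBF1":
    mandatory: ["PFX048"]
    forbidden: ["PFX055"]
  "MED6":
    mandatory: ["PFX049"]
    forbidden: ["PFX056"]
  "MED7":
    mandatory: ["PFX050"]
    forbidden: ["PFX057"]
  "PHD-finger":
    mandatory: ["PFX051"]
    forbidden: ["PFX058"]
  "Polycomb-EZ":
    mandatory: ["PFX052"]
    forbidden: ["PFX059"]
  "Rcd1-like":
    mandatory: ["PFX053"]
    forbidden: ["PFX060"]
  "SET":
    mandatory: ["PFX054"]
    forbidden: ["PFX061"]
  "Sigma70-like":
    mandatory: ["PFX055"]
    forbidden: ["PFX062"]
  "Sin3":
    mandatory: ["PFX056"]
    forbidden: ["PFX063"]
  "Sir2":
    mandatory: ["PFX057"]
    forbidden: ["PFX064"]
  "SNF2":
    mandatory: ["PFX058"]
    forbidden: ["PFX065"]
  "SOH1-like":
    mandatory: ["PFX059"]
    forbidden: ["PFX066"]
  "SWI/SNF-BAF60b":
    mandatory: ["PFX060"]
    forbidden: ["PFX067"]
  "SWI/SNF-SWI3":
    mandatory: ["PFX061"]
    forbidden: ["PFX068"]
  "TAZ":
    mandatory: ["PFX062"]
    forbidden: ["PFX069"]
  "TFb2":
    mandatory: ["PFX063"]
    forbidden: ["PFX070"]
  "TRAF-BTB":
    mandatory: ["PFX064"]
    forbidden: ["PFX071"]
  "VARL":
    mandatory: ["PFX065"]
    forbidden: []
  "VIP":
    mandatory: ["PFX066"]
    forbidden: []
  "mTERF-like":
    mandatory: ["PFX067"]
    forbidden: []
  "PBF-2-like":
    mandatory: ["PFX068"]
    forbidden: []
  "RB":
    mandatory: ["PFX069"]
    forbidden: []
  "CAMTA":
    mandatory: ["PFX070"]
    forbidden: []
  "CSD":
    mandatory: ["PFX071"]
    forbidden: []
  "DBP":
    mandatory: ["PFX072"]
    forbidden: []
  "EMF1":
    mandatory: ["PFX073"]
    forbidden: []
  "FAR1":
    mandatory: ["PFX074"]
    forbidden: []
  "GARP-ARR-B":
    mandatory: ["PFX075"]
    forbidden: []
  "GARP-G2-like":
    mandatory: ["PFX076"]
    forbidden: []
  "GIF":
    mandatory: ["PFX077"]
    forbidden: []
  "HRT":
    mandatory: ["PFX078"]
    forbidden: []
  "IWS1":
    mandatory: ["PFX079"]
    forbidden: []
  "NF-YA":
    mandatory: ["PFX080"]
    forbidden: []
  "NGATHA":
    mandatory: ["PFX081"]
    forbidden: []
  "RWP-RK":
    mandatory: ["PFX082"]
    forbidden: []
  "SPL-like":
    mandatory: ["PFX083"]
    forbidden: []
  "STAT":
    mandatory: ["PFX084"]
    forbidden: []
  "TUB-like":
    mandatory: ["PFX085"]
    forbidden: []
  "Zn-clus-like":
    mandatory: ["PFX086"]
    forbidden: []
synonyms:
  "NF-YC": "CCAAT-HAP5"
  "NF-YB": "CCAAT-HAP3"
  "ABI3/VP1": "B3"
  "ERF": "AP2-EREBP"
  "AP2/ERF-ERF": "AP2-EREBP"
  "WD-40": "PcG_FIE"
  "TUB": "TUBBY"
  "WDR": "PcG_FIE"
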