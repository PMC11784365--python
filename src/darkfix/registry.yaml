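# Curated registry of the seven known autotrophic CO2-fixation pathways and
# their diagnostic (key) genes.  EC numbers follow the standard enzyme
# nomenclature; KO ids are the conventional KEGG Orthology assignments used as
# the quantification currency (match by KO first, EC fallback).  Users may
# edit this file or supply their own via --registry.
#
# abundance_marker: the single key gene whose per-cell gene/transcript copy
#   number represents the pathway in abundance and correlation analyses.
# shared_with: other CO2-fixation pathways in which the same enzyme also
#   occurs; a gene with a non-empty shared_with is never exclusive evidence.
# companion_genes: additional critical genes required for a "complete" call,
#   empty by default and user-extensible per pathway.
pathways:
  rTCA:
    full_name: reductive tricarboxylic acid cycle
    key_genes:
      - symbol: aclA
        enzyme: ATP-citrate lyase
        ec: ["2.3.3.8"]
        ko: K15230
        abundance_marker: true
        shared_with: []
      - symbol: korA
        enzyme: 2-Oxoglutarate synthase
        ec: ["1.2.7.3"]
        ko: K00174
        shared_with: []
    companion_genes: []
  WLP:
    full_name: Wood-Ljungdahl pathway
    key_genes:
      - symbol: acsC/cdhE
        accepted_symbols: [acsC, cdhE]
        enzyme: Acetyl-CoA synthase
        ec: ["2.3.1.169", "2.1.1.245"]
        ko: K00197
        abundance_marker: true
        shared_with: []
      - symbol: cooS
        enzyme: CO dehydrogenase
        ec: ["1.2.7.4"]
        ko: K00198
        shared_with: []
    companion_genes: []
  Calvin:
    full_name: Calvin-Benson-Bassham cycle
    key_genes:
      - symbol: rbcL
        enzyme: RuBisCO
        ec: ["4.1.1.39"]
        ko: K01601
        abundance_marker: true
        shared_with: []
      - symbol: prkB
        enzyme: Phosphoribulokinase
        ec: ["2.7.1.19"]
        ko: K00855
        shared_with: []
    companion_genes: []
  DC/4-HB:
    full_name: dicarboxylate/4-hydroxybutyrate cycle
    key_genes:
      - symbol: abfD
        enzyme: 4-Hydroxybutyryl-CoA dehydratase
        ec: ["4.2.1.120"]
        ko: K14534
        shared_with: ["3-HP/4-HB"]
      - symbol: mdh
        enzyme: Malate dehydrogenase
        ec: ["1.1.1.37"]
        ko: K00024
        shared_with: [rTCA]
    companion_genes: []
  3-HP bicycle:
    full_name: 3-hydroxypropionate bicycle
    key_genes:
      - symbol: mcr
        enzyme: Malonyl-CoA reductase
        ec: ["1.2.1.75"]
        ko: K14468
        shared_with: ["3-HP/4-HB"]
      - symbol: pcs
        enzyme: Propionyl-CoA synthase
        ec: ["6.4.1.3"]
        ko: K14469
        shared_with: ["3-HP/4-HB"]
      - symbol: mcl
        enzyme: Malyl-CoA lyase
        ec: ["4.1.3.24"]
        ko: K08691
        shared_with: []
    companion_genes: []
  3-HP/4-HB:
    full_name: 3-hydroxypropionate/4-hydroxybutyrate cycle
    key_genes:
      - symbol: pccB
        enzyme: Acetyl-CoA/propionyl-CoA carboxylase
        ec: ["6.4.1.3"]
        ko: K01964
        shared_with: ["3-HP bicycle"]
      - symbol: mcm
        enzyme: Methylmalonyl-CoA mutase
        ec: ["5.4.99.2"]
        ko: K01847
        shared_with: ["3-HP bicycle"]
      - symbol: abfD
        enzyme: 4-Hydroxybutyryl-CoA dehydratase
        ec: ["4.2.1.120"]
        ko: K14534
        shared_with: ["DC/4-HB"]
    companion_genes: []
  rGlyP:
    full_name: reductive glycine pathway
    key_genes:
      - symbol: grdB
        enzyme: Glycine reductase
        ec: ["1.21.4.2"]
        ko: K10670
        abundance_marker: true
        shared_with: []
      - symbol: fchA
        enzyme: Methenyl-THF cyclohydrolase
        ec: ["3.5.4.9"]
        ko: K01491
        shared_with: []
    companion_genes: []

# Genes outside the seven pathways consulted by the chemoautotrophy check:
# photosynthetic reaction-centre (puf operon) vs sulfur-oxidation genes.
accessory_genes:
  pufM: {enzyme: Photosynthetic reaction centre subunit M, ko: K08929, ec: []}
  pufL: {enzyme: Photosynthetic reaction centre subunit L, ko: K08928, ec: []}
  tsd: {enzyme: Thiosulfate dehydrogenase, ko: K19713, ec: ["1.8.2.2"]}
  soxZ: {enzyme: Sulfur-oxidizing protein SoxZ, ko: K17227, ec: []}
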