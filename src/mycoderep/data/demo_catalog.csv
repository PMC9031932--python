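name,formula,mw,uv_maxima,taxon,fungal,source_db,record_id,activity,doi,ms2_cosine
"1,4-Bis(piperidin-1-ylmethyl)piperazine-2,5-dione",C16H28N4O2,,,Aspergillus terreus,True,DNP,,,,
"3b-(b-D-glucopyranosyloxy)olean-12-ene-23,28,30-trioic acid",C36H54O12,678.81,,Aspergillus amstelodami,True,Nmrdata,1331571,anti-melanogenic and anti-allergic activity,10.1002/cbdv.201900237,
Aspergilasine B,C42H49NO13,775.84,202;240,Aspergillus flavipes,True,Nmrdata,999923,,10.1021/acs.orglett.7b02146,
Unguisin A,C40H54N8O7,758.92,290;281;274;219,Aspergillus unguis,True,Nmrdata,29553,anion receptor with high affinity for phosphate,10.1021/np980539z,
Aspergilol A,C34H32O9,584.62,196;293;452,Aspergillus versicolor,True,Nmrdata,895659,antioxidant,10.1016/j.tet.2015.10.038,
Aspergilol B,C34H32O9,584.61,194;293;462,Aspergillus,True,DNP,,antioxidant,10.1016/j.tet.2015.10.038,
Aspergilol G,C34H32O9,584.61,206;265;295;458,Aspergillus,True,DNP,,,10.1016/J.BMCL.2017.01.032,
Territrem B,C29H34O9,526.57,195;220;236;330;284,Aspergillus terreus,True,GNPS,CCMSLIB00005436075,acetylcholinesterase inhibitor,10.3390/md12126113,0.70
Lovastatin,C24H36O5,404.54,231;238;247,Aspergillus terreus,True,GNPS,CCMSLIB00000852214,HMG-CoA reductase inhibitor,10.1080/10826068.2020.1805624,0.76
Aspernolide D,C24H26O9,458.46,290,Aspergillus terreus RCBC1002,True,Nmrdata,152713,,10.1248/cpb.58.1221,
Terretonin G,C27H38O9,506.58,END_ABSORPTION,Aspergillus sp. OPMF00272,True,Nmrdata,809567,antimicrobial vs Gram-positive bacteria,10.1038/ja.2014.46,
Epichloenin A,C46H74N12O18,1083.15,,Epichloe festucae,True,DNP,,fungal growth signal,10.1371/journal.ppat.1003332,
Astalluminoxide,C60H66AlN9O9,1084.22,201;222;272;349,Aspergillus terreus BCC51799,True,NP-Atlas,NPA032177,moderate cytotoxicity,10.1016/j.tet.2020.131496,
Austamide,C21H21N3O3,363.41,234;256;282;392,Aspergillus ustus,True,DNP,,toxic to ducklings,10.1016/s0040-4039(01)97170-9,
Circumdatin B,C20H17N3O4,363.37,284;358,Aspergillus ochraceus,True,DNP,,,10.1021/jo981536u,
Asperimide A,C22H21NO4,363.41,229;278;360,Aspergillus terreus,True,NP-Atlas,NPA028229,,10.1016/j.fitote.2018.10.011,
Cosmochlorin A,C18H18Cl2O4,369.24,323,Cosmospora vilior IM2-155,True,DNP,NPA030107,moderate antimicrobial,10.1016/j.phytol.2016.09.007,
Cosmochlorin B,C18H18Cl2O4,369.24,230;290,Cosmospora vilior IM2-155,True,DNP,NPA030108,osteoclast formation promoter,10.1016/j.phytol.2016.09.007,
Cosmochlorin C,C18H18Cl2O4,369.24,323,Cosmospora vilior IM2-155,True,DNP,NPA030109,antimicrobial,10.1016/j.phytol.2016.09.007,
Penicillixanthone,C16H10Cl2O6,369.15,230;294;369,Penicillium sp. PSU-RSPG99,True,DNP,NPA008373,,10.1016/j.tet.2014.05.105,
Nidulin,C20H17Cl3O5,443.70,267,Aspergillus unguis,True,GNPS,CCMSLIB00005436077,aromatase inhibitory and antimicrobial,10.1055/s-0031-1298228,0.70
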